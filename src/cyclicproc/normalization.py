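"""Single-cell intensity normalization and batch correction.

Covers the normalization toolbox for cyclic-immunofluorescence cell tables:

- intensity transforms (raw, log2(x+1), arcsinh(x/c))
- scikit-learn column scalers (standard, min-max, max-abs, robust, quantile,
  power)
- RESTORE-style background thresholds: markers expressed in mutually
  exclusive cell populations form L-shaped joint distributions; the
  expression of a marker in cells positive for its exclusive partner is
  background.  Exclusivity is scored by the minor/major singular-value ratio
  of the standardized two-column matrix, pairs are selected above data-driven
  cut-offs (0.5 per core / 0.66 globally, with fallbacks 0.2 / 0.5), and the
  per-marker threshold is the median over partners of a high quantile of the
  marker in partner-positive cells.
- RESTORE scale: below-threshold cells get a random value in (0, 0.02);
  above-threshold cells are mapped affinely onto [0.02, 1].
- reverse-compartment thresholds: Q3 of the marker in the compartment
  opposite its expected localization.
- ComBat empirical-Bayes location/scale batch adjustment, parameterizable on
  control-tissue subsets (same / sampled / all training modes), and
  mean-only regress-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import preprocessing as skprep

from cyclicproc.qc_metrics import ThresholdRecord

ARCSINH_COFACTOR = 5.0


# ---------------------------------------------------------------- transforms

def transform_intensity(values: np.ndarray, kind: str = "raw",
                        cofactor: float = ARCSINH_COFACTOR) -> np.ndarray:
    """Elementwise intensity transform: raw, log2(x+1), or arcsinh(x/c)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative intensities")
    if kind == "raw":
        return values.copy()
    if kind == "log2":
        return np.log2(values + 1.0)
    if kind == "arcsinh":
        return np.arcsinh(values / cofactor)
    raise ValueError(f"unknown transform {kind!r}")


_SCALERS = {
    "standard": skprep.StandardScaler,
    "minmax": skprep.MinMaxScaler,
    "maxabs": skprep.MaxAbsScaler,
    "robust": skprep.RobustScaler,
    "quantile": skprep.QuantileTransformer,
    "power": skprep.PowerTransformer,
}


def apply_scaler(values: np.ndarray, kind: str = "standard",
                 random_state: int = 0) -> np.ndarray:
    """Apply a scikit-learn column scaler to a 1-D or 2-D value array."""
    if kind not in _SCALERS:
        raise ValueError(f"unknown scaler {kind!r}; choose from {sorted(_SCALERS)}")
    arr = np.asarray(values, dtype=float)
    x = arr.reshape(-1, 1) if arr.ndim == 1 else arr
    for j in range(x.shape[1]):
        col = x[:, j]
        if kind in ("standard", "minmax", "maxabs", "robust", "power") and \
                len(np.unique(col)) < 2:
            warnings.warn(f"column {j}: fewer than 2 distinct values; "
                          f"{kind} scaling is degenerate", stacklevel=2)
    if kind == "quantile":
        scaler = skprep.QuantileTransformer(
            n_quantiles=min(1000, x.shape[0]), output_distribution="uniform",
            random_state=random_state)
    else:
        scaler = _SCALERS[kind]()
    out = scaler.fit_transform(x)
    return out.ravel() if arr.ndim == 1 else out


# ------------------------------------------------------------- RESTORE pairs

@dataclass(frozen=True)
class ExclusivePair:
    """A mutually exclusive marker pair with its exclusivity R-value."""

    marker_a: str
    marker_b: str
    r_value: float
    scope: str = "global"  # core | global

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ValueError("a marker cannot pair with itself")
        if not 0.0 <= self.r_value <= 1.0:
            raise ValueError("r_value must lie in [0, 1]")
        if self.scope not in ("core", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")


def exclusivity_score(x: np.ndarray, y: np.ndarray) -> float:
    """Exclusivity R-value of two marker columns.

    Both columns are standardized (mean 0, sd 1) and the singular values
    σ1 ≥ σ2 of the n×2 matrix are computed; the score is σ2/σ1 ∈ [0, 1].
    Co-expressed pairs are near rank-1 (score → 0); for a bivariate normal
    pair of correlation r the score is sqrt((1−r)/(1+r)).  Mutually
    exclusive (L-shaped) pairs are strongly anti-correlated within the
    expressing populations and score high.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("columns differ in length")
    if len(x) < 100:
        warnings.warn(f"only {len(x)} cells; exclusivity score is unstable",
                      stacklevel=2)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant marker column")
    m = np.column_stack([(x - x.mean()) / sx, (y - y.mean()) / sy])
    s = np.linalg.svd(m, compute_uv=False)
    return float(s[1] / s[0])


#: (primary, fallback) exclusivity cut-offs by scope
PAIR_CUTOFFS = {"core": (0.5, 0.2), "global": (0.66, 0.5)}


def select_exclusive_pairs(table: pd.DataFrame, markers: list[str],
                           scope: str = "global",
                           cutoffs: tuple[float, float] | None = None,
                           ) -> tuple[dict[str, list[ExclusivePair]], list[str]]:
    """Select exclusive partners for every marker.

    For each marker, partners scoring above the primary cut-off are kept;
    if none reach it, the fallback cut-off applies.  Markers with no partner
    even at the fallback are returned as unnormalizable.

    Returns (marker -> partner pairs, unnormalizable markers).
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    primary, fallback = cutoffs if cutoffs is not None else PAIR_CUTOFFS[scope]

    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            scores[(a, b)] = exclusivity_score(table[a].to_numpy(),
                                               table[b].to_numpy())

    pairs: dict[str, list[ExclusivePair]] = {}
    unnormalizable: list[str] = []
    for m in markers:
        partner_scores = []
        for other in markers:
            if other == m:
                continue
            key = (m, other) if (m, other) in scores else (other, m)
            partner_scores.append((other, scores[key]))
        selected = [(o, s) for o, s in partner_scores if s > primary]
        if not selected:
            selected = [(o, s) for o, s in partner_scores if s > fallback]
        if not selected:
            unnormalizable.append(m)
            continue
        pairs[m] = [ExclusivePair(m, o, s, scope=scope) for o, s in selected]
    return pairs, unnormalizable


def restore_threshold(table: pd.DataFrame, marker: str,
                      partners: list[ExclusivePair],
                      partner_positive_quantile: float = 0.75,
                      threshold_quantile: float = 0.995,
                      min_cells: int = 20) -> ThresholdRecord:
    """RESTORE background threshold for one marker.

    For each exclusive partner, cells in the partner's top intensity
    quartile are taken as partner-positive — by exclusivity, the marker's
    signal there is pure background — and the candidate threshold is the
    ``threshold_quantile`` of the marker in that subpopulation.  The final
    threshold is the median candidate over partners.
    """
    if not partners:
        raise ValueError(f"marker {marker!r}: no exclusive partners")
    candidates = []
    mvals = table[marker].to_numpy(dtype=float)
    for pair in partners:
        partner = pair.marker_b if pair.marker_a == marker else pair.marker_a
        pvals = table[partner].to_numpy(dtype=float)
        cut = np.quantile(pvals, partner_positive_quantile)
        sub = mvals[pvals > cut]
        if len(sub) < min_cells:
            warnings.warn(
                f"marker {marker!r}, partner {partner!r}: only {len(sub)} "
                f"partner-positive cells; candidate skipped", stacklevel=2)
            continue
        candidates.append(float(np.quantile(sub, threshold_quantile)))
    if not candidates:
        raise ValueError(
            f"marker {marker!r}: every partner candidate was skipped")
    return ThresholdRecord(marker, float(np.median(candidates)),
                           provenance="restore", scope="cell_mean")


def restore_scale(values: np.ndarray, t: ThresholdRecord,
                  seed: int) -> np.ndarray:
    """RESTORE scale normalization onto (0, 1].

    Cells at or below the threshold get a seeded uniform random value in
    (0, 0.02); cells above it are mapped affinely from [threshold, max] onto
    [0.02, 1], so the brightest cell maps to exactly 1 and order above the
    threshold is preserved.
    """
    values = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    out = np.empty_like(values)
    below = values <= t.value
    out[below] = rng.uniform(1e-6, 0.02, size=int(below.sum()))
    above = ~below
    if above.any():
        vmax = values[above].max()
        if vmax == t.value:
            out[above] = 1.0
        else:
            out[above] = 0.02 + (values[above] - t.value) / (vmax - t.value) * 0.98
    return out


def reverse_compartment_threshold(table: pd.DataFrame, marker: str,
                                  expected_compartment: str,
                                  quantile: float = 0.75) -> ThresholdRecord:
    """Background threshold from the reverse subcellular compartment.

    A marker localized to the nucleus should show only background in the
    cytoplasm (and vice versa); the threshold is the third quartile of the
    marker's intensity there.
    """
    reverse = {"nucleus": "cytoplasm", "cytoplasm": "nucleus"}.get(
        expected_compartment)
    if reverse is None:
        raise ValueError(
            f"expected_compartment must be nucleus or cytoplasm, "
            f"got {expected_compartment!r}")
    col = f"{marker}_{reverse}"
    if col not in table.columns:
        raise ValueError(f"table lacks column {col!r}")
    vals = table[col].dropna().to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError(f"no {reverse} measurements for marker {marker!r}")
    return ThresholdRecord(marker, float(np.quantile(vals, quantile)),
                           provenance="reverse_quantile", scope="cell_mean")


# ------------------------------------------------------------------- ComBat

@dataclass
class BatchModel:
    """Fitted location/scale batch-adjustment parameters.

    ``gamma[batch]`` and ``delta[batch]`` are per-feature location shifts and
    scale factors (on standardized data); ``training_mode`` records which
    cells parameterized the fit: ``same`` (one control core), ``sampled``
    (cells pooled from several control cores), or ``all`` (every cell).
    """

    features: list[str]
    batches: list[str]
    grand_mean: np.ndarray = field(repr=False, default=None)
    pooled_sd: np.ndarray = field(repr=False, default=None)
    gamma: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    delta: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    training_mode: str = "all"
    training_index: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for b, d in self.delta.items():
            if np.any(d <= 0):
                raise ValueError(f"non-positive scale factor in batch {b}")


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Parametric empirical-Bayes iteration for one batch (ref: location/scale
    model with normal prior on gamma, inverse-gamma prior on delta^2)."""
    n = (~np.isnan(sdat)).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[None, :]) ** 2, axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)))
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _aprior(d_hat):
    m, s2 = np.mean(d_hat), np.var(d_hat, ddof=1) if len(d_hat) > 1 else 0.0
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0 + m**2


def _bprior(d_hat):
    m, s2 = np.mean(d_hat), np.var(d_hat, ddof=1) if len(d_hat) > 1 else 0.0
    return (m * s2 + m**3) / s2 if s2 > 0 else m


def fit_batch_model(table: pd.DataFrame, batch_col: str, features: list[str],
                    training_mask: np.ndarray | None = None,
                    training_mode: str = "all",
                    shrink: bool = True) -> BatchModel:
    """Fit location/scale batch-adjustment parameters on training cells.

    Per feature the training data is standardized (grand mean, pooled
    within-batch sd); per batch the standardized mean γ̂ and variance δ̂² are
    estimated and — with ``shrink=True`` — shrunk by parametric empirical
    Bayes (normal prior on γ, inverse-gamma prior on δ²) toward the across-
    feature prior, stabilizing estimates for sparse batches.
    """
    batches = sorted(table[batch_col].astype(str).unique())
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    if training_mask is None:
        training_mask = np.ones(len(table), dtype=bool)
    train = table.loc[training_mask]
    batch_of = train[batch_col].astype(str).to_numpy()
    for b in batches:
        if not (batch_of == b).any():
            raise ValueError(f"batch {b!r} has no training cells")

    x = train[features].to_numpy(dtype=float)
    n_total = x.shape[0]
    n_per = np.array([(batch_of == b).sum() for b in batches], dtype=float)

    batch_means = np.stack([x[batch_of == b].mean(axis=0) for b in batches])
    grand_mean = (n_per[:, None] * batch_means).sum(axis=0) / n_total
    resid = x - batch_means[[batches.index(b) for b in batch_of]]
    pooled_var = (resid**2).sum(axis=0) / n_total
    if np.any(pooled_var == 0):
        zero = [features[j] for j in np.nonzero(pooled_var == 0)[0]]
        raise ValueError(f"zero-variance features in training data: {zero}")
    pooled_sd = np.sqrt(pooled_var)

    z = (x - grand_mean[None, :]) / pooled_sd[None, :]

    gamma: dict[str, np.ndarray] = {}
    delta: dict[str, np.ndarray] = {}
    for i, b in enumerate(batches):
        zb = z[batch_of == b]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1) if zb.shape[0] > 1 else np.ones(zb.shape[1])
        d_hat = np.maximum(d_hat, 1e-12)
        if shrink and len(features) > 1:
            g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1) + 1e-12)
            a, b_pr = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b_pr)
        else:
            g_star, d_star = g_hat, d_hat
        gamma[b] = g_star
        delta[b] = np.sqrt(np.maximum(d_star, 1e-12))

    return BatchModel(features=list(features), batches=batches,
                      grand_mean=grand_mean, pooled_sd=pooled_sd,
                      gamma=gamma, delta=delta, training_mode=training_mode,
                      training_index=np.nonzero(training_mask)[0])


def apply_batch_model(table: pd.DataFrame, batch_col: str,
                      model: BatchModel) -> pd.DataFrame:
    """Apply fitted batch adjustments to every cell of the table."""
    out = table.copy()
    x = table[model.features].to_numpy(dtype=float)
    z = (x - model.grand_mean[None, :]) / model.pooled_sd[None, :]
    batch_of = table[batch_col].astype(str).to_numpy()
    for b in np.unique(batch_of):
        if b not in model.gamma:
            raise ValueError(f"batch {b!r} was not present at fit time")
        rows = batch_of == b
        z[rows] = (z[rows] - model.gamma[b][None, :]) / model.delta[b][None, :]
    adjusted = z * model.pooled_sd[None, :] + model.grand_mean[None, :]
    out[model.features] = adjusted
    return out


def combat_adjust(table: pd.DataFrame, batch_col: str, features: list[str],
                  training_mode: str = "all",
                  control_core_ids: list[str] | None = None,
                  core_col: str = "core_id",
                  shrink: bool = True) -> tuple[pd.DataFrame, BatchModel]:
    """ComBat-style batch adjustment with control-tissue parameterization.

    Training modes: ``all`` fits on every cell; ``same`` on a single control
    core present in every batch (first of ``control_core_ids``); ``sampled``
    on cells pooled from the designated control cores.  The fitted shifts
    and scales are then applied batch-wise to all cells.  A single batch
    passes through unchanged.
    """
    batches = table[batch_col].astype(str).unique()
    if len(batches) < 2:
        return table.copy(), BatchModel(features=list(features),
                                        batches=sorted(batches.astype(str)),
                                        grand_mean=np.zeros(len(features)),
                                        pooled_sd=np.ones(len(features)),
                                        gamma={}, delta={},
                                        training_mode=training_mode)
    if training_mode == "all":
        mask = np.ones(len(table), dtype=bool)
    elif training_mode in ("same", "sampled"):
        if not control_core_ids:
            raise ValueError(f"training mode {training_mode!r} needs control_core_ids")
        cores = control_core_ids[:1] if training_mode == "same" else control_core_ids
        mask = table[core_col].astype(str).isin([str(c) for c in cores]).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells in control cores {cores}")
    else:
        raise ValueError(f"unknown training mode {training_mode!r}")

    model = fit_batch_model(table, batch_col, features, training_mask=mask,
                            training_mode=training_mode, shrink=shrink)
    return apply_batch_model(table, batch_col, model), model


def regress_out_batch(table: pd.DataFrame, batch_col: str,
                      features: list[str]) -> pd.DataFrame:
    """Mean-only batch correction: per feature and batch, subtract the batch
    mean and add the grand mean; variances are untouched."""
    out = table.copy()
    x = table[features].to_numpy(dtype=float)
    batch_of = table[batch_col].astype(str).to_numpy()
    grand = x.mean(axis=0)
    for b in np.unique(batch_of):
        rows = batch_of == b
        x[rows] = x[rows] - x[rows].mean(axis=0)[None, :] + grand[None, :]
    out[features] = x
    return out
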