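"""Monte-Carlo null models for the cell-to-vessel proximity distribution.

A shift in the proximity distribution between two samples can in principle be
produced by (1) a change in cell–vessel attraction, (2) a change in cell
number, or (3) a change in vessel morphology.  The three null constructions
here dissect these factors:

``reposition_observed``
    redistributes the observed cells uniformly over extravascular ROI pixel
    centres of the same map — destroys attraction, keeps number and map;
``matched_number``
    places a caller-chosen common number of cells uniformly on each map —
    destroys attraction *and* number differences, keeps the map;
``all_pixels``
    the exact distance distribution of every extravascular ROI pixel — the
    n → ∞ limit of uniform placement, a pure property of vessel morphology.

Placements are uniform over extravascular pixel *centres* (not continuous
positions), which makes ``all_pixels`` the exact population that the two
random nulls sample from.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from vesselprox.core import CellSet, RegionOfInterest, VesselMask
from vesselprox.proximity import DistanceField, cell_distances, compute_distance_field

log = logging.getLogger("vesselprox")

__all__ = [
    "NullEnsemble",
    "DistributionComparison",
    "AttractionFit",
    "null_reposition_observed",
    "null_matched_number",
    "null_all_pixels",
    "compare",
    "two_sample_comparison",
    "attribute_shift",
    "fit_attraction",
    "ks_statistic",
]

_MODELS = ("reposition_observed", "matched_number", "all_pixels")


@dataclass
class NullEnsemble:
    """Replicate distance samples (μm) under one null construction."""

    model: str
    replicates: list[np.ndarray]
    n_cells: int
    seed: int | None

    _pooled: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown null model {self.model!r}")
        if len(self.replicates) < 1:
            raise ValueError("ensemble needs at least one replicate")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def pooled(self) -> np.ndarray:
        """All replicate distances pooled and sorted."""
        if self._pooled is None:
            self._pooled = np.sort(np.concatenate(self.replicates)) if any(
                r.size for r in self.replicates
            ) else np.empty(0)
        return self._pooled

    def pooled_ecdf(self, x) -> np.ndarray:
        """Right-continuous pooled ECDF evaluated at ``x``."""
        pooled = self.pooled()
        return np.searchsorted(pooled, np.asarray(x, dtype=float), side="right") / max(
            pooled.size, 1
        )

    def mean(self) -> float:
        return float(self.pooled().mean())


def _extravascular_population(
    mask: VesselMask, roi: RegionOfInterest | None, allow_intravascular: bool = False
) -> tuple[DistanceField, np.ndarray]:
    """Distance field plus the distances of all candidate placement pixels."""
    dfield = compute_distance_field(mask, roi)
    if allow_intravascular:
        pop = dfield.values[dfield.roi]
    else:
        pop = dfield.extravascular_distances()
    if pop.size == 0:
        raise ValueError("ROI contains no extravascular pixels")
    return dfield, pop


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Counter-based stream: replicate ``r`` is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def _sample_null(
    model: str,
    pop: np.ndarray,
    n_cells: int,
    n_reps: int,
    seed: int,
) -> NullEnsemble:
    if n_cells == 0:
        log.warning("null %s: n_cells = 0, replicates are empty", model)
    reps = []
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        idx = rng.integers(0, pop.size, size=n_cells)
        reps.append(pop[idx])
    return NullEnsemble(model=model, replicates=reps, n_cells=n_cells, seed=seed)


def null_reposition_observed(
    cells: CellSet,
    mask: VesselMask,
    roi: RegionOfInterest | None,
    n_reps: int = 1000,
    seed: int = 0,
    allow_intravascular: bool = False,
) -> NullEnsemble:
    """Uniformly reposition the observed cells within their own map.

    Each replicate places ``len(cells)`` points uniformly at random (with
    replacement) over extravascular ROI pixel centres and records their
    nearest-vessel distances.  If attraction alone explained an observed
    proximity shift, this null would erase it while preserving cell number
    and vessel morphology.
    """
    _, pop = _extravascular_population(mask, roi, allow_intravascular)
    return _sample_null("reposition_observed", pop, len(cells), n_reps, seed)


def null_matched_number(
    mask: VesselMask,
    roi: RegionOfInterest | None,
    n_cells: int,
    n_reps: int = 1000,
    seed: int = 0,
    allow_intravascular: bool = False,
) -> NullEnsemble:
    """Uniformly place a caller-chosen number of cells on a map.

    Applying the same ``n_cells`` to two maps isolates the contribution of
    cell number: with a common count, any residual distribution difference
    must come from the maps themselves.
    """
    _, pop = _extravascular_population(mask, roi, allow_intravascular)
    return _sample_null("matched_number", pop, n_cells, n_reps, seed)


def null_all_pixels(
    field: DistanceField, roi: RegionOfInterest | None = None
) -> NullEnsemble:
    """The exact proximity distribution of all extravascular ROI pixels.

    Deterministic single "replicate": the distance value at every
    extravascular pixel centre inside the ROI.  This is the exact
    distribution of one uniformly random extravascular position and the
    n → ∞ limit of the two sampling nulls.
    """
    roi_raster = field.roi if roi is None else (
        roi.raster if roi.is_raster else None
    )
    if roi_raster is None:
        raise ValueError("null_all_pixels needs a raster ROI (or the field's own)")
    pop = field.values[roi_raster & (field.values > 0)]
    if pop.size == 0:
        raise ValueError("ROI contains no extravascular pixels")
    return NullEnsemble(
        model="all_pixels", replicates=[pop.copy()], n_cells=pop.size, seed=None
    )


# ---------------------------------------------------------------------------
# comparison statistics


def ks_statistic(sample: np.ndarray, pooled_sorted: np.ndarray) -> np.ndarray:
    """sup_x |F_sample(x) − G(x)| against the discrete ECDF of ``pooled_sorted``.

    ``sample`` may be 1D (one sample) or 2D (one sample per row; rows are
    evaluated independently and a vector of statistics is returned).  Exact
    for tied, discrete distributions: the supremum over the real line of the
    difference of the two right-continuous step functions.
    """
    s = np.asarray(sample, dtype=float)
    one = s.ndim == 1
    s = np.sort(np.atleast_2d(s), axis=1)
    m, n = s.shape
    P = pooled_sorted.size
    g_right = np.searchsorted(pooled_sorted, s, side="right") / P
    g_left = np.searchsorted(pooled_sorted, s, side="left") / P
    k_hi = np.arange(1, n + 1) / n
    k_lo = np.arange(0, n) / n
    d_plus = (k_hi[None, :] - g_right).max(axis=1)    # F overshoots G at a jump
    d_minus = (g_left - k_lo[None, :]).max(axis=1)    # G leads F just below a jump
    d = np.maximum(np.maximum(d_plus, d_minus), 0.0)
    return d[0] if one else d


@dataclass
class DistributionComparison:
    """KS distance, mean difference and Monte-Carlo p-value vs a null."""

    ks_statistic: float
    mean_diff: float
    mc_p_value: float
    n_obs: int
    n_mc: int


def compare(
    obs: np.ndarray,
    null: NullEnsemble,
    n_mc: int = 999,
    seed: int = 0,
) -> DistributionComparison:
    """Compare an observed distance sample with a null ensemble.

    The statistic is the KS distance between the observed ECDF and the
    null's pooled ECDF.  The p-value is Monte-Carlo: ``n_mc`` synthetic
    samples of ``len(obs)`` points are drawn (with replacement) from the
    pooled null distribution and scored with the same statistic; with the
    add-one correction ``p = (1 + #{D_b >= D_obs}) / (n_mc + 1)``, so the
    smallest attainable p is ``1/(n_mc+1)``.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.size == 0:
        raise ValueError("observed sample is empty")
    if n_mc < 19:
        raise ValueError("n_mc < 19 gives a p-value resolution coarser than 0.05")
    pooled = null.pooled()
    if pooled.size == 0:
        raise ValueError("null ensemble is degenerate (no distances)")
    d_obs = float(ks_statistic(obs, pooled))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    draws = pooled[rng.integers(0, pooled.size, size=(n_mc, obs.size))]
    d_mc = ks_statistic(draws, pooled)
    p = (1.0 + int(np.count_nonzero(d_mc >= d_obs))) / (n_mc + 1.0)
    return DistributionComparison(
        ks_statistic=d_obs,
        mean_diff=float(obs.mean() - pooled.mean()),
        mc_p_value=float(p),
        n_obs=obs.size,
        n_mc=n_mc,
    )


def two_sample_comparison(
    a: np.ndarray, b: np.ndarray, n_mc: int = 999, seed: int = 0
) -> DistributionComparison:
    """Two-sample KS with a Monte-Carlo permutation p-value (pooled resampling)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_mc < 19:
        raise ValueError("n_mc < 19 gives a p-value resolution coarser than 0.05")
    pooled_all = np.concatenate([a, b])
    d_obs = float(ks_statistic(a, np.sort(b)))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled_all)
        d = ks_statistic(perm[: a.size], np.sort(perm[a.size:]))
        if d >= d_obs:
            count += 1
    p = (1.0 + count) / (n_mc + 1.0)
    return DistributionComparison(
        ks_statistic=d_obs,
        mean_diff=float(a.mean() - b.mean()),
        mc_p_value=float(p),
        n_obs=a.size,
        n_mc=n_mc,
    )


# ---------------------------------------------------------------------------
# factor attribution


def attribute_shift(
    obs_a: np.ndarray,
    obs_b: np.ndarray,
    mask_a: VesselMask,
    mask_b: VesselMask,
    roi_a: RegionOfInterest | None,
    roi_b: RegionOfInterest | None,
    n_reps: int = 1000,
    seed: int = 0,
    n_mc: int = 999,
    common_n: int | None = None,
    verdict_alpha: float = 0.01,
    morphology_ks_threshold: float = 0.05,
    number_rel_threshold: float = 0.2,
) -> pd.DataFrame:
    """Dissect a between-sample proximity shift into its candidate causes.

    Runs the three null constructions on both maps and reports:

    (i)   *attraction test* — each observed sample against the repositioning
          null of its own map (Monte-Carlo KS p-value);
    (ii)  *number test* — matched-number nulls with a common cell count on
          both maps (the pooled distributions are compared; the observed cell
          counts are reported alongside);
    (iii) *morphology test* — the exact all-extravascular-pixel distance
          distributions of the two maps against each other (a deterministic
          population-level KS distance).

    The verdict column names the factor(s) implicated: morphology when the
    population KS exceeds ``morphology_ks_threshold``; attraction when either
    map's repositioning test rejects at ``verdict_alpha`` (conservative by
    default because two per-map tests feed a single verdict); number when the
    observed cell counts differ by more than ``number_rel_threshold``
    (relative).  The verdict logic is this package's codification of the
    three-control reasoning and is labelled as such in the output.
    """
    obs_a = np.asarray(obs_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    field_a = compute_distance_field(mask_a, roi_a)
    field_b = compute_distance_field(mask_b, roi_b)
    pix_a = null_all_pixels(field_a)
    pix_b = null_all_pixels(field_b)

    # (i) attraction: observed vs reposition null, per map
    rep_a = _sample_null("reposition_observed", pix_a.pooled(), obs_a.size, n_reps, seed)
    rep_b = _sample_null("reposition_observed", pix_b.pooled(), obs_b.size, n_reps,
                         seed + 1)
    cmp_a = compare(obs_a, rep_a, n_mc=n_mc, seed=seed + 2)
    cmp_b = compare(obs_b, rep_b, n_mc=n_mc, seed=seed + 3)

    # (ii) number: common n on both maps
    n_common = common_n if common_n is not None else min(obs_a.size, obs_b.size)
    match_a = _sample_null("matched_number", pix_a.pooled(), n_common, n_reps, seed + 4)
    match_b = _sample_null("matched_number", pix_b.pooled(), n_common, n_reps, seed + 5)
    ks_number = float(ks_statistic(match_a.pooled(), match_b.pooled()))

    # (iii) morphology: exact pixel populations
    ks_morph = float(ks_statistic(pix_a.pooled(), pix_b.pooled()))

    # observed between-map shift, for reference
    shift = two_sample_comparison(obs_a, obs_b, n_mc=n_mc, seed=seed + 6)

    n_a, n_b = obs_a.size, obs_b.size
    number_differs = abs(n_a - n_b) > number_rel_threshold * max(n_a, n_b)
    attraction_differs = min(cmp_a.mc_p_value, cmp_b.mc_p_value) < verdict_alpha
    morphology_differs = ks_morph > morphology_ks_threshold

    factors = []
    if morphology_differs:
        factors.append("vascular morphology")
    if attraction_differs:
        factors.append("cell-vessel attraction")
    if number_differs:
        factors.append("cell number")
    verdict = " + ".join(factors) if factors else "none"

    rows = [
        {"test": "observed_shift", "statistic": shift.ks_statistic,
         "p_value": shift.mc_p_value, "mean_diff_um": shift.mean_diff,
         "detail": f"obs A (n={n_a}) vs obs B (n={n_b}), two-sample MC KS"},
        {"test": "attraction_A", "statistic": cmp_a.ks_statistic,
         "p_value": cmp_a.mc_p_value, "mean_diff_um": cmp_a.mean_diff,
         "detail": "obs A vs reposition null on map A"},
        {"test": "attraction_B", "statistic": cmp_b.ks_statistic,
         "p_value": cmp_b.mc_p_value, "mean_diff_um": cmp_b.mean_diff,
         "detail": "obs B vs reposition null on map B"},
        {"test": "number", "statistic": ks_number, "p_value": np.nan,
         "mean_diff_um": match_a.mean() - match_b.mean(),
         "detail": f"matched-number nulls, common n={n_common}, pooled KS"},
        {"test": "morphology", "statistic": ks_morph, "p_value": np.nan,
         "mean_diff_um": pix_a.mean() - pix_b.mean(),
         "detail": "all-extravascular-pixel distributions, population KS"},
    ]
    table = pd.DataFrame(rows)
    table["verdict"] = verdict
    table.attrs["verdict"] = verdict
    table.attrs["factors"] = factors
    table.attrs["note"] = (
        "verdict rule is this package's codification of the three-control logic"
    )
    return table


# ---------------------------------------------------------------------------
# attraction-parameter estimation


@dataclass
class AttractionFit:
    """Maximum-likelihood fit of the uniform/attraction mixture.

    The observed distance density is modelled as
    ``p(d) ∝ (1−α)·g(d) + α·g(d)·exp(−d/λ)/Z`` where ``g`` is the map's
    extravascular pixel distance density and ``Z = E_g[exp(−d/λ)]``
    normalizes the attraction component.  ``alpha`` is the mixture weight of
    the attraction component (this differs from a generator that weights
    pixels by ``(1−α) + α·exp(−d/λ)`` only by a monotone reparametrization of
    the weight; λ is identical in both forms).
    """

    alpha: float
    lam: float
    loglik: float
    converged: bool
    message: str = ""


def _neg_loglik(params: np.ndarray, d: np.ndarray, pop: np.ndarray) -> float:
    alpha, lam = params
    z = float(np.exp(-pop / lam).mean())
    w = np.exp(-d / lam) / z
    dens = (1.0 - alpha) + alpha * w
    return -float(np.log(np.maximum(dens, 1e-300)).sum())


def fit_attraction(
    distances: np.ndarray,
    pixel_null: NullEnsemble,
    max_lam: float | None = None,
) -> AttractionFit:
    """Fit the mixture weight and attraction length scale by maximum likelihood.

    ``pixel_null`` must be the all-pixels null of the same map the cells were
    observed on; its pooled distances serve as the empirical reference
    density ``g`` (whose contribution to the log-likelihood is constant in
    the parameters, so only the mixture factor is optimized).  L-BFGS-B from
    a small grid of starts; bounds ``α ∈ [0, 1]``,
    ``λ ∈ [0.1 μm, max_lam]`` (default: twice the largest pixel distance).
    Non-convergence and non-identifiable inputs are flagged, not raised.
    """
    d = np.asarray(distances, dtype=float)
    pop = pixel_null.pooled()
    if d.size == 0 or pop.size == 0:
        raise ValueError("need non-empty distances and pixel null")
    if np.ptp(pop) == 0:
        warnings.warn(
            "pixel distance distribution is degenerate (single value): "
            "attraction parameters are not identifiable",
            RuntimeWarning,
        )
        return AttractionFit(alpha=0.0, lam=1.0, loglik=0.0, converged=False,
                             message="degenerate pixel distribution")
    if max_lam is None:
        max_lam = 2.0 * float(pop.max())
    bounds = [(0.0, 1.0), (0.1, max_lam)]
    starts = [(a0, l0) for a0 in (0.2, 0.5, 0.9)
              for l0 in (2.0, 10.0, min(40.0, max_lam))]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik, x0=np.asarray(x0), args=(d, pop),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, lam = best.x
    return AttractionFit(
        alpha=float(alpha), lam=float(lam), loglik=-float(best.fun),
        converged=bool(best.success), message=str(best.message),
    )
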