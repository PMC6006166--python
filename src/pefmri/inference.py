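"""Group-level permutation inference on COPE maps.

One-way ANOVA (or pairwise pseudo-t) across groups at each voxel, with the
pooled within-group variance image spatially smoothed (3 mm FWHM by default)
before forming the statistic, as is standard for modest sample sizes.
Statistic maps are enhanced with threshold-free cluster enhancement (TFCE,
E = 0.5, H = 2, 6-connectivity) and family-wise error is controlled by the
permutation distribution of the image-wide maximum TFCE value, with the
observed labelling included in the null set.  Significant-voxel sets feed
cluster-mean extraction, planned one-tailed pairwise comparisons and
Spearman symptom correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, generate_binary_structure, label
from scipy.stats import spearmanr

__all__ = [
    "voxelwise_stat",
    "tfce",
    "permutation_fwe",
    "InferenceResult",
    "extract_cluster_means",
    "ClusterSummary",
    "symptom_correlation",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_subject_by_voxel(copes: np.ndarray, mask: np.ndarray | None):
    """Normalise input to (n_subjects, n_voxels) plus the spatial mask."""
    copes = np.asarray(copes, dtype=float)
    if copes.ndim == 2 and mask is None:
        return copes, None
    if mask is None:
        raise ValueError("mask required for spatial input")
    if copes.ndim != mask.ndim + 1:
        raise ValueError("copes must be (n_subjects, *mask.shape)")
    return copes[:, mask], mask


def _group_indicators(groups: np.ndarray) -> tuple[list[str], np.ndarray]:
    names = sorted(set(groups))
    codes = np.array([names.index(g) for g in groups])
    return names, codes


def _smooth_variance(
    var_flat: np.ndarray, mask: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Gaussian-smooth variance images inside the mask, edge-renormalised.

    ``var_flat`` is (n_images, n_mask_voxels); smoothing acts on the spatial
    axes only.
    """
    if fwhm_mm <= 0:
        return var_flat
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    n_img = var_flat.shape[0]
    stack = np.zeros((n_img,) + mask.shape)
    stack[:, mask] = var_flat
    sm = gaussian_filter(stack, sigma=(0,) + (sigma_vox,) * mask.ndim)
    norm = gaussian_filter(mask.astype(float), sigma=sigma_vox)
    sm = sm / np.maximum(norm, 1e-12)
    return sm[:, mask]


def _stat_maps(
    copes_flat: np.ndarray,
    label_matrix: np.ndarray,
    codes_values: np.ndarray,
    mode: str,
    mask: np.ndarray | None,
    fwhm_mm: float,
    voxel_size_mm: float,
    one_tailed: bool = True,
) -> np.ndarray:
    """Pseudo-F (or pseudo-t) maps for a batch of labelings.

    ``label_matrix`` is (n_labelings, n_subjects) of integer group codes.
    Returns (n_labelings, n_voxels).
    """
    n_lab, n = label_matrix.shape
    n_vox = copes_flat.shape[1]
    k = codes_values.max() + 1
    grand = copes_flat.mean(axis=0)
    sst = ((copes_flat - grand) ** 2).sum(axis=0)

    ssb = np.zeros((n_lab, n_vox))
    means = []
    counts = []
    for g in range(k):
        ind = (label_matrix == g).astype(float)  # (n_lab, n)
        ng = ind.sum(axis=1)
        if np.any(ng < 2):
            raise ValueError("every group needs at least 2 subjects")
        mg = (ind @ copes_flat) / ng[:, None]
        ssb += ng[:, None] * (mg - grand) ** 2
        means.append(mg)
        counts.append(ng)
    ssw = np.maximum(sst - ssb, 0.0)
    if mode == "anova":
        msw = ssw / (n - k)
        if mask is not None:
            msw = _smooth_variance(msw, mask, fwhm_mm, voxel_size_mm)
        stat = (ssb / (k - 1)) / np.maximum(msw, 1e-300)
    elif mode == "pairwise":
        if k != 2:
            raise ValueError("pairwise mode needs exactly two groups")
        s2 = ssw / (n - 2)
        if mask is not None:
            s2 = _smooth_variance(s2, mask, fwhm_mm, voxel_size_mm)
        se = np.sqrt(np.maximum(s2, 1e-300) * (1.0 / counts[0] + 1.0 / counts[1])[:, None])
        stat = (means[0] - means[1]) / se
        if not one_tailed:
            stat = np.abs(stat)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return stat


def voxelwise_stat(
    copes: np.ndarray,
    groups,
    variance_smooth_fwhm_mm: float = 3.0,
    mask: np.ndarray | None = None,
    voxel_size_mm: float = 2.0,
    mode: str = "anova",
    one_tailed: bool = True,
) -> np.ndarray:
    """Voxelwise pseudo-F (ANOVA) or pseudo-t (two-group) statistic map.

    The pooled within-group variance image is Gaussian-smoothed at the given
    FWHM before entering the denominator; FWHM 0 reproduces the classical
    statistic exactly.  With spatial input, returns a map of the mask's
    shape (zero outside); with (n_subjects, n_voxels) input and no mask,
    smoothing is skipped and a flat statistic vector is returned.
    """
    groups = np.asarray(groups)
    flat, mask = _as_subject_by_voxel(copes, mask)
    names, codes = _group_indicators(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    stat = _stat_maps(
        flat, codes[None, :], codes, mode, mask, variance_smooth_fwhm_mm, voxel_size_mm, one_tailed
    )[0]
    if mask is None:
        return stat
    out = np.zeros(mask.shape)
    out[mask] = stat
    return out


def tfce(
    stat_map: np.ndarray,
    mask: np.ndarray | None = None,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    TFCE(v) = sum over thresholds h of extent(h, v)^E * h^H * dh, where
    extent is the size of v's 6-connected supra-threshold cluster at height
    h.  Only positive statistic values are enhanced.  ``dh`` defaults to
    max(stat)/100.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map contains non-finite values")
    if E < 0 or H < 0:
        raise ValueError("E and H must be >= 0")
    if mask is None:
        mask = np.ones(stat_map.shape, dtype=bool)
    work = np.where(mask, stat_map, 0.0)
    mx = work.max()
    if mx <= 0:
        return np.zeros(stat_map.shape)
    if dh is None:
        dh = mx / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    out = np.zeros(stat_map.shape)
    structure = generate_binary_structure(stat_map.ndim, 1)  # 6-connectivity in 3D
    h = dh
    while h <= mx + 1e-12:
        supra = work >= h
        labels, n = label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels]
        out[supra] += (extent[supra] ** E) * (h**H) * dh
        h += dh
    return out


def _tfce_batch(stats: np.ndarray, mask: np.ndarray, E: float, H: float, dh_ref: float) -> np.ndarray:
    """TFCE for a stack of maps (n_maps, *mask.shape) on a shared threshold grid.

    The grid runs from ``dh_ref`` up to the global maximum in steps of
    ``dh_ref`` (the observed map's max/100 in permutation use), so every
    map's integral is covered.  Connectivity never crosses the map axis.
    """
    n_maps = stats.shape[0]
    work = np.where(mask[None], stats, 0.0)
    out = np.zeros_like(work)
    gmax = work.max()
    if gmax <= 0 or dh_ref <= 0:
        return out
    structure = np.zeros((3,) * (mask.ndim + 1), dtype=bool)
    structure[1] = generate_binary_structure(mask.ndim, 1)
    h = dh_ref
    while h <= gmax + 1e-12:
        supra = work >= h
        labels, n = label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels]
        out[supra] += (extent[supra] ** E) * (h**H) * dh_ref
        h += dh_ref
    return out


def _n_distinct_labelings(counts: list[int]) -> int:
    total = sum(counts)
    out = math.factorial(total)
    for c in counts:
        out //= math.factorial(c)
    return out


def _enumerate_labelings(codes: np.ndarray) -> np.ndarray:
    """All distinct assignments of the multiset of group codes to positions."""
    from sympy.utilities.iterables import multiset_permutations

    return np.array(list(multiset_permutations(list(codes))))


@dataclass
class InferenceResult:
    """Permutation/TFCE inference over one ROI."""

    stat_map: np.ndarray
    tfce_map: np.ndarray
    p_corrected: np.ndarray  # 1.0 outside the mask
    p_uncorrected: np.ndarray
    significant: np.ndarray  # boolean, p_corrected <= alpha
    mask: np.ndarray
    n_perm: int
    seed: int
    mode: str
    alpha: float
    exhaustive: bool = False

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def min_p(self) -> float:
        return float(self.p_corrected[self.mask].min())


def permutation_fwe(
    copes: np.ndarray,
    groups,
    mask: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    mode: str = "anova",
    one_tailed: bool = True,
    variance_smooth_fwhm_mm: float = 3.0,
    voxel_size_mm: float = 2.0,
    E: float = 0.5,
    H: float = 2.0,
    alpha: float = 0.05,
) -> InferenceResult:
    """Max-statistic FWE-corrected permutation inference with TFCE.

    Group labels are shuffled without restriction; corrected p at voxel v is
    the proportion of the null set (observed labelling plus ``n_perm``
    permutations) whose maximum TFCE over the mask reaches the observed
    TFCE(v).  When fewer distinct labelings exist than ``n_perm``, all of
    them are enumerated instead and the result is flagged exhaustive.
    Voxels with corrected p equal to ``alpha`` count as significant.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    groups = np.asarray(groups)
    copes = np.asarray(copes, dtype=float)
    mask = np.asarray(mask, dtype=bool)

    # crop to the mask bounding box: connectivity and smoothing are local
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(mask)
    )
    mask_c = mask[bbox]
    copes_c = copes[(slice(None),) + bbox]
    flat = copes_c[:, mask_c]

    names, codes = _group_indicators(groups)
    counts = [int((codes == g).sum()) for g in range(len(names))]
    n_distinct = _n_distinct_labelings(counts)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        all_lab = _enumerate_labelings(codes)
        # put the observed labelling first
        obs_row = np.flatnonzero((all_lab == codes).all(axis=1))[0]
        order = np.concatenate([[obs_row], np.delete(np.arange(len(all_lab)), obs_row)])
        labelings = all_lab[order]
        n_used = len(labelings) - 1
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        labelings = np.vstack([codes[None, :], perms])
        n_used = n_perm

    stats = _stat_maps(
        flat, labelings, codes, mode, mask_c, variance_smooth_fwhm_mm, voxel_size_mm, one_tailed
    )
    stat_stack = np.zeros((len(labelings),) + mask_c.shape)
    stat_stack[:, mask_c] = stats

    obs_max = max(stat_stack[0].max(), 0.0)
    dh_ref = obs_max / 100.0 if obs_max > 0 else 0.0
    tfce_stack = _tfce_batch(stat_stack, mask_c, E, H, dh_ref)
    tfce_flat = tfce_stack[:, mask_c]

    obs_tfce = tfce_flat[0]
    null_max = tfce_flat.max(axis=1)  # includes observed at row 0
    denom = n_used + 1
    p_corr = (null_max[:, None] >= obs_tfce[None, :]).sum(axis=0) / denom
    p_unc = (tfce_flat >= obs_tfce[None, :]).sum(axis=0) / denom

    def _embed(vals, fill):
        full = np.full(mask.shape, fill)
        sub = np.full(mask_c.shape, fill)
        sub[mask_c] = vals
        full[bbox] = sub
        return full

    stat_map = _embed(stats[0], 0.0)
    tfce_map = _embed(obs_tfce, 0.0)
    p_map = _embed(p_corr, 1.0)
    pu_map = _embed(p_unc, 1.0)
    sig = (p_map <= alpha) & mask
    return InferenceResult(
        stat_map=stat_map,
        tfce_map=tfce_map,
        p_corrected=p_map,
        p_uncorrected=pu_map,
        significant=sig,
        mask=mask,
        n_perm=n_used,
        seed=seed,
        mode=mode,
        alpha=alpha,
        exhaustive=exhaustive,
    )


@dataclass
class ClusterSummary:
    """Cluster-mean COPEs over a significant-voxel set, with planned tests."""

    subject_means: np.ndarray
    groups: np.ndarray
    group_means: dict[str, float]
    group_sds: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]  # one-tailed, first > second
    n_voxels: int
    empty: bool = False


def _one_tailed_perm_p(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """P(mean(a) - mean(b) as large as observed) under label exchange."""
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    na = len(a)
    perms = np.array([rng.permutation(pooled) for _ in range(n_perm)])
    diffs = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    return float((1 + (diffs >= obs - 1e-12).sum()) / (n_perm + 1))


def extract_cluster_means(
    copes: np.ndarray,
    significant: np.ndarray,
    groups,
    comparisons: list[tuple[str, str]] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> ClusterSummary:
    """Per-subject mean COPE over the significant voxels and planned tests.

    ``comparisons`` lists ordered pairs (g1, g2) testing the one-tailed
    hypothesis mean(g1) > mean(g2) by a two-sample permutation test.  An
    empty significant set returns an explicit empty summary, not an error.
    """
    groups = np.asarray(groups)
    copes = np.asarray(copes, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    names = sorted(set(groups))
    if not significant.any():
        return ClusterSummary(
            subject_means=np.full(len(groups), np.nan),
            groups=groups,
            group_means={g: np.nan for g in names},
            group_sds={g: np.nan for g in names},
            pairwise_p={},
            n_voxels=0,
            empty=True,
        )
    if copes.ndim == 2 and significant.ndim == 1:
        means = copes[:, significant].mean(axis=1)
    else:
        means = copes[:, significant].mean(axis=1)
    gmeans = {g: float(means[groups == g].mean()) for g in names}
    gsds = {g: float(means[groups == g].std(ddof=1)) for g in names}
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rng = np.random.default_rng(seed)
    pw = {}
    for g1, g2 in comparisons:
        pw[(g1, g2)] = _one_tailed_perm_p(means[groups == g1], means[groups == g2], n_perm, rng)
    return ClusterSummary(
        subject_means=means,
        groups=groups,
        group_means=gmeans,
        group_sds=gsds,
        pairwise_p=pw,
        n_voxels=int(significant.sum()),
    )


def symptom_correlation(cluster_means: np.ndarray, symptom_scores: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with two-sided p.

    Returns (nan, nan) for constant input.
    """
    x = np.asarray(cluster_means, dtype=float)
    y = np.asarray(symptom_scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired observations required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
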