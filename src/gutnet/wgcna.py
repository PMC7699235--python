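"""Weighted co-expression module analysis (WGCNA-style) for omics features.

Pipeline: screen outlier samples by hierarchical clustering; choose a
soft-thresholding power beta so that the weighted network a_ij = |cor|^beta
approximates scale-free topology (signed R^2 of the log-log degree
distribution fit > 0.8); compute the unsigned topological overlap matrix
(TOM); cluster features on 1 - TOM with average linkage and a static tree
cut; label modules by color in decreasing size order (turquoise, blue,
brown, ...) with gray reserved for unassigned features; summarize each
module by its eigengene (first principal component of the module profile
matrix) and report module membership (MM), per-trait biomarker
significance (BS) and module-trait correlations, with p-values from the
Student-t transform at n-2 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .corrnet import correlation_pvalue
from .io import TraitTable
from .preprocess import ZScoreMatrix

logger = logging.getLogger(__name__)

# classic color vocabulary, by decreasing module size; gray = unassigned
COLOR_ORDER = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
GRAY = "gray"

__all__ = [
    "ScaleFreeFit",
    "PowerSweep",
    "OutlierScreen",
    "WGCNAModel",
    "sample_outlier_screen",
    "scale_free_fit",
    "soft_adjacency",
    "pick_power",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "eigengenes",
    "membership_and_significance",
    "module_trait",
    "fit_wgcna",
    "COLOR_ORDER",
    "GRAY",
]


def _values(z) -> pd.DataFrame:
    if isinstance(z, ZScoreMatrix):
        return z.values
    return pd.DataFrame(z)


# ---------------------------------------------------------------------------
# sample outlier screen


@dataclasses.dataclass
class OutlierScreen:
    linkage: np.ndarray
    kept: list
    flagged: list
    cut_height: float


def sample_outlier_screen(
    z: ZScoreMatrix | pd.DataFrame, cut_height: float | None = None
) -> OutlierScreen:
    """Average-linkage clustering of samples; flag those merging above cut.

    Distances are Euclidean between sample profiles. With an explicit
    ``cut_height`` the tree is cut there and every sample outside the
    largest resulting cluster is flagged. By default the cut is placed at
    median + 8 * MAD of the merge heights, a conservative rule that keeps
    every sample of a homogeneous cohort while isolating gross outliers
    (e.g. a sample with several-fold inflated noise); if no merge exceeds
    the cut, all samples are kept.
    """
    data = _values(z)
    n = data.shape[1]
    if n < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    x = data.to_numpy(dtype=float).T  # samples x features
    link = hierarchy.linkage(x, method="average", metric="euclidean")
    heights = link[:, 2]
    if cut_height is None:
        med = float(np.median(heights))
        mad = float(np.median(np.abs(heights - med)))
        cut = med + 8.0 * 1.4826 * max(mad, 1e-12)
    else:
        cut = float(cut_height)
    samples = list(data.columns)
    if heights.max() <= cut:
        return OutlierScreen(link, samples, [], cut)
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    main = sizes.idxmax()
    kept = [s for s, l in zip(samples, labels) if l == main]
    flagged = [s for s, l in zip(samples, labels) if l != main]
    if not kept:
        raise ValueError("outlier cut removed every sample")
    return OutlierScreen(link, kept, flagged, cut)


# ---------------------------------------------------------------------------
# scale-free fit and soft power selection


@dataclasses.dataclass
class ScaleFreeFit:
    signed_r2: float
    slope: float
    n_bins_used: int

    @property
    def ok(self) -> bool:
        return self.n_bins_used >= 3


def scale_free_fit(degrees, n_bins: int = 10) -> ScaleFreeFit:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned (by exact value when there are at most
    ``n_bins`` distinct values, else into ``n_bins`` equal-width bins);
    log10 of the per-bin frequency is regressed on log10 of the per-bin
    mean connectivity. R^2 is the squared correlation; the sign flips to
    negative when the slope is positive (more hubs than non-hubs is not a
    scale-free decay). Fewer than 3 occupied bins -> undefined (``ok``
    False).
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return ScaleFreeFit(np.nan, np.nan, 0)
    uniq = np.unique(k)
    if uniq.size <= n_bins:
        centers = uniq
        freq = np.array([(k == u).sum() for u in uniq], dtype=float)
    else:
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        centers, freq = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.any():
                centers.append(k[mask].mean())
                freq.append(mask.sum())
        centers = np.asarray(centers, dtype=float)
        freq = np.asarray(freq, dtype=float)
    occupied = freq > 0
    centers, freq = centers[occupied], freq[occupied]
    if centers.size < 3 or np.allclose(centers, centers[0]):
        return ScaleFreeFit(np.nan, np.nan, int(centers.size))
    logk = np.log10(centers)
    logp = np.log10(freq / freq.sum())
    slope, intercept = np.polyfit(logk, logp, 1)
    c = np.corrcoef(logk, logp)[0, 1]
    r2 = float(c * c)
    signed = -r2 if slope > 0 else r2
    return ScaleFreeFit(signed, float(slope), int(centers.size))


def soft_adjacency(z: ZScoreMatrix | pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |cor(i, j)|^beta, zero diagonal."""
    data = _values(z)
    r = np.corrcoef(data.to_numpy(dtype=float))
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=data.index, columns=data.index)


@dataclasses.dataclass
class PowerSweep:
    beta: int
    table: pd.DataFrame  # power, signed_r2, slope, mean_connectivity
    reached_target: bool


def pick_power(
    z: ZScoreMatrix | pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> PowerSweep:
    """Sweep candidate powers; pick the smallest with signed R^2 > target.

    If no candidate reaches the target the argmax is returned with a
    warning (``reached_target`` False). Mean connectivity is reported per
    power and is non-increasing in beta since |r| <= 1.
    """
    data = _values(z)
    r = np.abs(np.clip(np.corrcoef(data.to_numpy(dtype=float)), -1.0, 1.0))
    np.fill_diagonal(r, 0.0)
    rows = []
    for beta in powers:
        a = r**beta
        k = a.sum(axis=1)
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": int(beta),
                "signed_r2": fit.signed_r2,
                "slope": fit.slope,
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    reached = table["signed_r2"] > r2_target
    if reached.any():
        beta = int(reached.idxmax())  # first True = smallest power
        return PowerSweep(beta, table, True)
    if table["signed_r2"].isna().all():
        beta = int(table.index[0])
        logger.warning("scale-free fit undefined at every power; using beta=%d", beta)
        return PowerSweep(beta, table, False)
    beta = int(table["signed_r2"].idxmax())
    logger.warning(
        "no power reached signed R^2 > %.2f; using argmax beta=%d", r2_target, beta
    )
    return PowerSweep(beta, table, False)


# ---------------------------------------------------------------------------
# module detection


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


DEFAULT_CUT_GRID = (0.93, 0.95, 0.96, 0.97, 0.98, 0.99)


def _static_cut(
    link: np.ndarray, index: pd.Index, cut: float, min_size: int
) -> pd.Series:
    """Cut the dendrogram at ``cut``; clusters below ``min_size`` go gray."""
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    keep = sizes.index[sizes >= min_size]
    colors = pd.Series(GRAY, index=index, dtype=object)
    for ci, lab in enumerate(keep):
        colors[labels == lab] = f"cluster_{ci}"
    return colors


def _unit_rows(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return xc / norms


def _refine_modules(
    data: pd.DataFrame,
    colors: pd.Series,
    kme_min: float,
    merge_cor: float,
    min_module_size: int,
    max_rounds: int = 6,
) -> pd.Series:
    """Eigengene-guided refinement of a raw tree-cut assignment.

    Alternates three classic steps until stable: (1) merge modules whose
    eigengenes correlate above ``merge_cor`` (union-find, transitive);
    (2) recompute eigengenes; (3) reassign every feature to the module
    whose eigengene carries its largest joint-regression loading,
    provided its plain module membership |kME| reaches ``kme_min``,
    otherwise gray. The joint regression makes the assignment robust to
    chance correlation between module eigengenes at small sample sizes.
    """
    xn = _unit_rows(data.to_numpy(dtype=float))
    for _ in range(max_rounds):
        mes = eigengenes(data, colors)
        if not len(mes):
            break
        names = list(mes.index)
        if len(names) > 1:
            cor = np.abs(np.corrcoef(mes.to_numpy()))
            parent = list(range(len(names)))

            def find(i: int) -> int:
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if cor[i, j] > merge_cor:
                        pi, pj = find(i), find(j)
                        if pi != pj:
                            parent[max(pi, pj)] = min(pi, pj)
            remap = {names[i]: names[find(i)] for i in range(len(names))}
            colors = colors.map(lambda c: remap.get(c, c))
            mes = eigengenes(data, colors)
            names = list(mes.index)
        mn = _unit_rows(mes.to_numpy())
        kme = xn @ mn.T
        loadings = np.linalg.lstsq(mn.T, xn.T, rcond=None)[0].T
        best = np.abs(loadings).argmax(axis=1)
        marginal = np.abs(kme[np.arange(len(best)), best])
        new = pd.Series(
            [
                names[b] if v >= kme_min else GRAY
                for b, v in zip(best, marginal)
            ],
            index=data.index,
        )
        if new.equals(colors):
            colors = new
            break
        colors = new
    sizes = colors.value_counts()
    small = [c for c in sizes.index if c != GRAY and sizes[c] < min_module_size]
    colors = colors.copy()
    colors[colors.isin(small)] = GRAY
    return colors


def _explained_score(
    data: pd.DataFrame, colors: pd.Series, penalty: float
) -> float:
    """Sum of members' squared eigengene correlations, penalized per module."""
    mes = eigengenes(data, colors)
    if not len(mes):
        return -1.0
    xn = _unit_rows(data.to_numpy(dtype=float))
    total = 0.0
    positions = {f: i for i, f in enumerate(data.index)}
    for color in mes.index:
        me = mes.loc[color].to_numpy()
        mn = (me - me.mean()) / np.linalg.norm(me - me.mean())
        idx = [positions[f] for f in colors.index[colors == color]]
        total += float(((xn[idx] @ mn) ** 2).sum())
    return total - penalty * len(mes)


def _relabel_by_size(colors: pd.Series) -> pd.Series:
    sizes = colors[colors != GRAY].value_counts()
    positions = {f: i for i, f in enumerate(colors.index)}
    order = sorted(
        sizes.index,
        key=lambda c: (
            -sizes[c],
            min(positions[f] for f in colors.index[colors == c]),
        ),
    )
    remap = {}
    for i, c in enumerate(order):
        remap[c] = COLOR_ORDER[i] if i < len(COLOR_ORDER) else f"module_{i}"
    return colors.map(lambda c: remap.get(c, GRAY))


def detect_modules(
    z: ZScoreMatrix | pd.DataFrame,
    beta: float,
    min_module_size: int = 20,
    cut_height: float | None = None,
    refine: bool = True,
    min_core_size: int = 12,
    kme_min: float = 0.5,
    merge_cor: float = 0.8,
    model_penalty: float = 15.0,
) -> pd.Series:
    """Cluster features on TOM dissimilarity and assign module colors.

    Average-linkage hierarchical clustering on 1 - TOM with a static tree
    cut. With an explicit ``cut_height`` that single cut is used; by
    default a small grid of cut heights is evaluated and the solution
    maximizing the eigengene-explained variance (penalized per module,
    so spurious splinters do not pay) is kept. With ``refine`` the raw
    cut's cores (>= ``min_core_size``) are polished by eigengene merging
    and kME reassignment; clusters below ``min_module_size`` are always
    relabeled gray. Colors are assigned by decreasing module size
    (turquoise, blue, brown, ...), breaking size ties by the first member
    feature's position in the input.
    """
    data = _values(z)
    if data.shape[0] < min_module_size:
        raise ValueError("fewer features than min_module_size")
    a = soft_adjacency(data, beta)
    tom = tom_similarity(a)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")

    cuts = [cut_height] if cut_height is not None else list(DEFAULT_CUT_GRID)
    core_min = min_core_size if refine else min_module_size
    best, best_score = None, -np.inf
    for cut in cuts:
        colors = _static_cut(link, data.index, cut, core_min)
        if refine:
            colors = _refine_modules(
                data, colors, kme_min, merge_cor, min_module_size
            )
        else:
            sizes = colors.value_counts()
            small = [
                c for c in sizes.index if c != GRAY and sizes[c] < min_module_size
            ]
            colors = colors.copy()
            colors[colors.isin(small)] = GRAY
        if len(cuts) == 1:
            best = colors
            break
        score = _explained_score(data, colors, model_penalty)
        if score > best_score:
            best_score, best = score, colors
    assert best is not None
    if (best == GRAY).all():
        logger.warning("all %d features unassigned (gray)", data.shape[0])
    return _relabel_by_size(best)


# ---------------------------------------------------------------------------
# eigengenes, membership, trait association


def module_eigengene(z: ZScoreMatrix | pd.DataFrame, members) -> pd.Series:
    """First principal component of the module's feature x sample submatrix.

    Unit norm; sign oriented so the mean member-eigengene correlation is
    positive.
    """
    data = _values(z)
    sub = data.loc[list(members)].to_numpy(dtype=float)
    if sub.shape[0] == 0:
        raise ValueError("module has no members")
    centered = sub - sub.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    me = vt[0]
    me = me / np.linalg.norm(me)
    cors = []
    for row in centered:
        sd = row.std()
        if sd > 0 and me.std() > 0:
            cors.append(np.corrcoef(row, me)[0, 1])
    if cors and np.mean(cors) < 0:
        me = -me
    return pd.Series(me, index=data.columns)


def eigengenes(z: ZScoreMatrix | pd.DataFrame, colors: pd.Series) -> pd.DataFrame:
    """Module eigengene matrix (modules x samples), gray excluded."""
    data = _values(z)
    out = {}
    for color in colors.unique():
        if color == GRAY:
            continue
        members = colors.index[colors == color]
        out[color] = module_eigengene(data, members)
    order = [c for c in COLOR_ORDER if c in out] + sorted(
        k for k in out if k not in COLOR_ORDER
    )
    return pd.DataFrame(out).T.loc[order] if out else pd.DataFrame(
        columns=data.columns
    )


def _corr_with_p(
    x: pd.DataFrame, y: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Pearson correlation of each row of x with y (pairwise NaN dropping in y)."""
    mask = y.notna()
    n = int(mask.sum())
    if n < 4:
        raise ValueError("need at least 4 non-missing samples")
    yv = y[mask].to_numpy(dtype=float)
    if yv.std() == 0:
        return (
            pd.Series(np.nan, index=x.index),
            pd.Series(np.nan, index=x.index),
        )
    xv = x.loc[:, mask].to_numpy(dtype=float)
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    p = correlation_pvalue(r, n)
    return pd.Series(r, index=x.index), pd.Series(p, index=x.index)


def membership_and_significance(
    z: ZScoreMatrix | pd.DataFrame,
    mes: pd.DataFrame,
    traits: TraitTable,
) -> dict[str, pd.DataFrame]:
    """Module membership (feature vs ME) and biomarker significance (feature vs trait).

    Returns a dict with ``mm``/``mm_p`` (features x modules) and
    ``bs``/``bs_p`` (features x traits). Samples with a missing trait are
    dropped pairwise; a trait constant over its non-missing samples
    yields NaN columns.
    """
    data = _values(z)
    mm = pd.DataFrame(index=data.index, columns=mes.index, dtype=float)
    mm_p = mm.copy()
    for color in mes.index:
        r, p = _corr_with_p(data, mes.loc[color])
        mm[color], mm_p[color] = r, p
    trait_frame = traits.frame().loc[data.columns]
    bs = pd.DataFrame(index=data.index, columns=trait_frame.columns, dtype=float)
    bs_p = bs.copy()
    for trait in trait_frame.columns:
        y = trait_frame[trait]
        if y.notna().sum() < 4 or y.dropna().std() == 0:
            continue
        r, p = _corr_with_p(data, y)
        bs[trait], bs_p[trait] = r, p
    return {"mm": mm, "mm_p": mm_p, "bs": bs, "bs_p": bs_p}


def module_trait(
    mes: pd.DataFrame, traits: TraitTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengene vs trait correlations with two-sided p-values."""
    trait_frame = traits.frame().loc[mes.columns]
    r_out = pd.DataFrame(index=mes.index, columns=trait_frame.columns, dtype=float)
    p_out = r_out.copy()
    for trait in trait_frame.columns:
        y = trait_frame[trait]
        if y.notna().sum() < 4 or y.dropna().std() == 0:
            continue
        r, p = _corr_with_p(mes, y)
        r_out[trait], p_out[trait] = r, p
    return r_out, p_out


# ---------------------------------------------------------------------------
# orchestration


@dataclasses.dataclass
class WGCNAModel:
    """Fitted co-expression model: power, modules, eigengenes, associations."""

    beta: int
    power_sweep: pd.DataFrame
    colors: pd.Series
    mes: pd.DataFrame
    mm: pd.DataFrame
    mm_p: pd.DataFrame
    bs: pd.DataFrame
    bs_p: pd.DataFrame
    module_trait_r: pd.DataFrame
    module_trait_p: pd.DataFrame
    kept_samples: list

    @property
    def module_sizes(self) -> pd.Series:
        nongray = self.colors[self.colors != GRAY]
        return nongray.value_counts()

    @property
    def n_modules(self) -> int:
        return int((self.colors.unique() != GRAY).sum())


def fit_wgcna(
    z: ZScoreMatrix | pd.DataFrame,
    traits: TraitTable,
    powers=range(1, 21),
    r2_target: float = 0.8,
    beta: int | None = None,
    min_module_size: int = 20,
    cut_height: float | None = None,
    outlier_cut: float | None = None,
) -> WGCNAModel:
    """Run the full co-expression analysis on a z-scored feature matrix.

    ``beta`` overrides the automatic soft-power selection when given
    (e.g. to reproduce a published configuration).
    """
    data = _values(z)
    screen = sample_outlier_screen(data, cut_height=outlier_cut)
    data = data[screen.kept]
    sweep = pick_power(data, powers=powers, r2_target=r2_target)
    chosen = int(beta) if beta is not None else sweep.beta
    colors = detect_modules(
        data, chosen, min_module_size=min_module_size, cut_height=cut_height
    )
    mes = eigengenes(data, colors)
    sub_traits = TraitTable(
        traits.condition.loc[data.columns],
        traits.treatment.loc[data.columns],
    )
    if len(mes):
        tables = membership_and_significance(data, mes, sub_traits)
        mt_r, mt_p = module_trait(mes, sub_traits)
    else:
        empty = pd.DataFrame(index=data.index)
        tables = {"mm": empty, "mm_p": empty, "bs": empty, "bs_p": empty}
        mt_r = mt_p = pd.DataFrame()
    return WGCNAModel(
        beta=chosen,
        power_sweep=sweep.table,
        colors=colors,
        mes=mes,
        mm=tables["mm"],
        mm_p=tables["mm_p"],
        bs=tables["bs"],
        bs_p=tables["bs_p"],
        module_trait_r=mt_r,
        module_trait_p=mt_p,
        kept_samples=screen.kept,
    )
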