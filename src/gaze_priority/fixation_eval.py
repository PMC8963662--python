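"""Ground-truth fixation handling and the two evaluation procedures.

Evaluation route 1 — NSS: a priority map is z-scored with its own mean and
population standard deviation, and the normalized scanpath saliency is the
mean z-value at fixated pixels.  NSS = 0 is chance; NSS = 1 means fixated
locations sit one standard deviation above the map average.

Evaluation route 2 — patch-grid GLMM: each image is divided into an 8x6
grid (48 patches); per subject x image x patch, the binary response is
whether the subject's n-th fixation fell in the patch, and the predictors
are the patch-mean values of each candidate priority map (after histogram
matching to the image's fixation-density map, then table-wide min-max
normalization).  A logistic mixed model with the candidate maps as joint
fixed effects and scene/target groupings as random intercepts yields a
z-statistic per map — its unique contribution to fixation prediction at
that scanpath position.  Per-row clamp-at-zero normalized z's form the
weight table that summarizes how the factors trade off across the first
nine fixations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .priority_maps import PriorityMap, histogram_match

logger = logging.getLogger(__name__)

__all__ = [
    "Fixation",
    "FixationSequence",
    "FixationDensityMap",
    "ObservationTable",
    "GlmmResult",
    "WeightTable",
    "GlmmConvergenceError",
    "read_fixations",
    "write_fixations",
    "build_fdm",
    "nss",
    "select_fixation",
    "patch_means",
    "patch_feature_means",
    "build_observation_table",
    "fit_glmm",
    "weight_table",
    "GRID",
]

#: patch grid: (columns, rows) -> 48 patches
GRID: tuple[int, int] = (8, 6)


@dataclass(frozen=True)
class Fixation:
    x: float
    y: float
    index: int  # 1-based position in the scanpath (first post-onset fixation = 1)


@dataclass
class FixationSequence:
    """Ordered gaze points of one subject on one image.

    Indices are 1-based scanpath ordinals and must be strictly increasing;
    gaps are allowed (e.g. after upstream filtering).  Coordinates are
    pixels, 0-based, origin top-left.
    """

    subject_id: str
    image_id: str
    fixations: list[Fixation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        self.image_id = str(self.image_id)
        self.fixations = [
            f if isinstance(f, Fixation) else Fixation(*f) for f in self.fixations
        ]
        idx = [f.index for f in self.fixations]
        if any(i < 1 for i in idx):
            raise ValueError("fixation indices are 1-based")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("fixation indices must be strictly increasing")

    def at(self, n: int) -> Fixation | None:
        for f in self.fixations:
            if f.index == n:
                return f
        return None


@dataclass
class FixationDensityMap:
    """Smoothed, unit-mass raster of fixation locations."""

    values: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("FDM must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("FDM must sum to 1")

    def as_priority_map(self) -> PriorityMap:
        return PriorityMap(self.values, "other", {"fdm_sigma": self.sigma})


def read_fixations(path: str | Path) -> list[FixationSequence]:
    """Read a fixation table (CSV with header
    ``subject_id,image_id,fix_index,x,y``; extra columns such as
    duration_ms are ignored) into per-subject-per-image sequences."""
    df = pd.read_csv(path)
    required = {"subject_id", "image_id", "fix_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation file missing columns: {sorted(missing)}")
    out = []
    for (subj, img), grp in df.groupby(["subject_id", "image_id"], sort=True):
        grp = grp.sort_values("fix_index")
        out.append(
            FixationSequence(
                str(subj),
                str(img),
                [Fixation(float(r.x), float(r.y), int(r.fix_index)) for r in grp.itertuples()],
            )
        )
    return out


def write_fixations(seqs: Sequence[FixationSequence], path: str | Path) -> None:
    rows = [
        (s.subject_id, s.image_id, f.index, f.x, f.y)
        for s in seqs
        for f in s.fixations
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "image_id", "fix_index", "x", "y"]
    ).to_csv(path, index=False)


def build_fdm(
    seqs: Iterable[FixationSequence],
    shape: tuple[int, int],
    sigma: float | None = None,
    fixation_index: int | None = None,
) -> FixationDensityMap:
    """Fixation-density map: delta masses at fixation pixels convolved with
    an isotropic Gaussian and renormalized to unit mass.

    sigma defaults to height/24 (about one degree of visual angle at
    typical eye-tracking geometry).  ``fixation_index`` restricts the FDM
    to the n-th fixation of each sequence.  Raises on an empty fixation
    set.
    """
    h, w = shape
    if sigma is None:
        sigma = h / 24.0
    pts = []
    for s in seqs:
        for f in s.fixations:
            if fixation_index is None or f.index == fixation_index:
                pts.append((f.x, f.y))
    if not pts:
        raise ValueError("no fixations to build an FDM from")
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    acc = np.zeros((h, w), dtype=float)
    # separable form of the isotropic Gaussian: exp(-(dx^2+dy^2)/2s^2)
    for fx, fy in pts:
        gx = np.exp(-((xs - fx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - fy) ** 2) / (2 * sigma**2))
        acc += np.outer(gy, gx)
    return FixationDensityMap(acc / acc.sum(), sigma)


def nss(m: PriorityMap, fixations: Sequence[tuple[float, float]]) -> float:
    """Normalized scanpath saliency of a map against fixation locations.

    The map is standardized to zero mean and unit population standard
    deviation; the score is the mean standardized value at the fixated
    pixels (coordinates rounded to the nearest pixel).  A constant map has
    no spatial structure to score and returns 0 with a warning.
    """
    if len(fixations) == 0:
        raise ValueError("need at least one fixation")
    v = m.values
    # constancy via max == min: summation round-off can leave std() at a
    # tiny nonzero value on a constant raster, which would explode the z's
    if v.max() == v.min():
        logger.warning("constant map (variant %s): NSS defined as 0", m.variant)
        return 0.0
    sd = v.std()  # population SD
    z = (v - v.mean()) / sd
    h, w = z.shape
    total = 0.0
    for fx, fy in fixations:
        j = min(max(int(round(fx)), 0), w - 1)
        i = min(max(int(round(fy)), 0), h - 1)
        total += z[i, j]
    return total / len(fixations)


def select_fixation(
    seqs: Sequence[FixationSequence], n: int
) -> tuple[dict[tuple[str, str], tuple[float, float]], int]:
    """The n-th fixation of each (subject, image) pair, where it exists.

    Returns a mapping (subject_id, image_id) -> (x, y) plus the count of
    contributing pairs, the numerator of the per-index instance
    proportion.
    """
    if not (1 <= n <= 9):
        raise ValueError("fixation index must be in 1..9")
    picks: dict[tuple[str, str], tuple[float, float]] = {}
    for s in seqs:
        f = s.at(n)
        if f is not None:
            picks[(s.subject_id, s.image_id)] = (f.x, f.y)
    return picks, len(picks)


def _grid_edges(size: int, cells: int) -> np.ndarray:
    """Cell edges partitioning ``size`` pixels into ``cells`` cells of
    floor(size/cells) pixels each, remainder pixels folded into the last
    cell."""
    base = size // cells
    edges = np.arange(cells + 1) * base
    edges[-1] = size
    return edges


def patch_cell(
    x: float, y: float, shape: tuple[int, int], grid: tuple[int, int] = GRID
) -> int:
    """Row-major patch index of the pixel containing (x, y)."""
    cols, rows = grid
    h, w = shape
    xe = _grid_edges(w, cols)
    ye = _grid_edges(h, rows)
    j = min(max(int(np.searchsorted(xe, x, side="right") - 1), 0), cols - 1)
    i = min(max(int(np.searchsorted(ye, y, side="right") - 1), 0), rows - 1)
    return i * cols + j


def patch_means(
    m: PriorityMap, grid: tuple[int, int] = GRID
) -> np.ndarray:
    """Mean map value over each cell of a ``(columns, rows)`` grid covering
    the image; cells are equal-sized up to remainder pixels, which fold
    into the last row/column; values in row-major patch order."""
    cols, rows = grid
    h, w = m.shape
    xe = _grid_edges(w, cols)
    ye = _grid_edges(h, rows)
    out = np.empty(rows * cols, dtype=float)
    for i in range(rows):
        for j in range(cols):
            out[i * cols + j] = m.values[ye[i] : ye[i + 1], xe[j] : xe[j + 1]].mean()
    return out


@dataclass
class ObservationTable:
    """The (subject x image x patch) binary-fixation design matrix.

    ``data`` has one row per subject x image x patch — exactly
    n_images x n_subjects x 48 rows — with columns: subject_id, image_id,
    patch_index, fixated (0/1), contributing (whether the pair has an n-th
    fixation at all), one column per feature (patch-mean map values,
    min-max normalized to [0, 1] across the table), and any grouping
    columns (e.g. scene_type, target_category).
    ``fixation_index`` is the scanpath position the table was built for.
    """

    data: pd.DataFrame
    fixation_index: int
    features: list[str]
    groupings: list[str] = field(default_factory=list)

    def contributing(self) -> pd.DataFrame:
        """Rows of (subject, image) pairs that actually have the n-th
        fixation; the design the model is fit on."""
        return self.data[self.data["contributing"]]


def patch_feature_means(
    maps: Mapping[str, Mapping[str, PriorityMap]],
    fdms: Mapping[str, FixationDensityMap] | None = None,
    grid: tuple[int, int] = GRID,
) -> dict[tuple[str, str], np.ndarray]:
    """Per (image_id, feature): the 48 patch-mean map values, after
    histogram matching each map to its image's reference FDM when one is
    supplied.  Independent of fixation index, so compute once when
    building tables for several indices."""
    out = {}
    for img, per in maps.items():
        for f, m in per.items():
            if fdms is not None:
                m = histogram_match(m, fdms[img].as_priority_map())
            out[(img, f)] = patch_means(m, grid)
    return out


def build_observation_table(
    maps: Mapping[str, Mapping[str, PriorityMap]],
    seqs: Sequence[FixationSequence],
    n: int,
    fdms: Mapping[str, FixationDensityMap] | None = None,
    group_labels: Mapping[str, Mapping[str, str]] | None = None,
    grid: tuple[int, int] = GRID,
    match_to_fdm: bool = True,
    patch_features: Mapping[tuple[str, str], np.ndarray] | None = None,
) -> ObservationTable:
    """Assemble the GLMM design for fixation index ``n``.

    maps : per image_id, per feature name, a PriorityMap.
    seqs : fixation sequences; every (subject, image) pair appearing in
        them gets 48 rows.
    fdms : per-image reference fixation-density maps for histogram
        matching; built from ``seqs`` (all fixations, all subjects) when
        omitted.
    group_labels : per grouping name, a mapping image_id -> level (e.g.
        scene_type), copied onto the rows for use as random intercepts.

    Pipeline order (fixed, logged): histogram-match each map to its
    image's FDM -> patch means -> min-max normalize each feature column
    across the table.
    """
    feature_names = sorted({f for per in maps.values() for f in per})
    image_ids = sorted({s.image_id for s in seqs})
    subject_ids = sorted({s.subject_id for s in seqs})
    for img in image_ids:
        if img not in maps:
            raise KeyError(f"no maps supplied for image {img!r}")
        for f in feature_names:
            if f not in maps[img]:
                raise KeyError(f"image {img!r}: missing map for feature {f!r}")
    if fdms is None and match_to_fdm:
        fdms = {
            img: build_fdm(
                [s for s in seqs if s.image_id == img],
                maps[img][feature_names[0]].shape,
            )
            for img in image_ids
        }
    logger.debug(
        "observation table n=%d: histogram-match -> patch means -> "
        "table-wide min-max", n,
    )
    if patch_features is not None:
        pmeans = patch_features
    else:
        pmeans = patch_feature_means(maps, fdms if match_to_fdm else None, grid)

    picks, _ = select_fixation(seqs, n)
    shape_by_img = {img: maps[img][feature_names[0]].shape for img in image_ids}
    cols, rows = grid
    n_patch = cols * rows
    records = []
    pairs = sorted({(s.subject_id, s.image_id) for s in seqs})
    for subj, img in pairs:
        pick = picks.get((subj, img))
        fix_patch = (
            patch_cell(pick[0], pick[1], shape_by_img[img], grid)
            if pick is not None
            else -1
        )
        for patch in range(n_patch):
            records.append(
                (subj, img, patch, int(patch == fix_patch), pick is not None)
            )
    df = pd.DataFrame(
        records,
        columns=["subject_id", "image_id", "patch_index", "fixated", "contributing"],
    )
    for f in feature_names:
        df[f] = [
            pmeans[(img, f)][patch]
            for img, patch in zip(df["image_id"], df["patch_index"])
        ]
        lo, hi = df[f].min(), df[f].max()
        df[f] = (df[f] - lo) / (hi - lo) if hi > lo else 0.0
    groupings = []
    for gname, labels in (group_labels or {}).items():
        df[gname] = df["image_id"].map(lambda i: labels[i])
        groupings.append(gname)
    expected = len(image_ids) * len(subject_ids) * n_patch
    if len(df) != expected and len(pairs) == len(image_ids) * len(subject_ids):
        raise AssertionError("row-count identity violated")
    return ObservationTable(df, n, feature_names, groupings)


# ---------------------------------------------------------------------------
# GLMM

class GlmmConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass
class GlmmResult:
    """Fixed-effect summary of one logistic (mixed) model fit.

    ``table`` has one row per fixed effect (intercept included):
    feature, estimate, se, z, p.  ``random_effect_sd`` maps each grouping
    to its estimated random-intercept standard deviation.  z is
    estimate/se; p is the two-sided normal tail probability.
    """

    table: pd.DataFrame
    random_effect_sd: dict[str, float]
    fixation_index: int | None = None
    n_obs: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def z(self, feature: str) -> float:
        row = self.table[self.table["feature"] == feature]
        if row.empty:
            raise KeyError(feature)
        return float(row["z"].iloc[0])


def _check_design(X: np.ndarray, names: list[str]) -> None:
    sds = X.std(axis=0)
    const = [n for n, s in zip(names, sds) if s == 0]
    if const:
        raise ValueError(f"constant fixed-effect column(s): {const}")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError(
            "rank-deficient fixed-effect design (identical or collinear columns)"
        )


def fit_glmm(
    table: ObservationTable | pd.DataFrame,
    fixed: Sequence[str],
    random: Sequence[str] = (),
    *,
    re_variance: float | None = None,
    fe_prior_sd: float = 10.0,
    vcp_prior_sd: float = 3.0,
) -> GlmmResult:
    """Logistic (mixed) regression of patch fixation on priority-map
    features.

    All ``fixed`` features enter jointly, so each z-statistic measures a
    feature's unique contribution given the others.  Each name in
    ``random`` adds a random intercept per level of that column.  With no
    random terms — or ``re_variance=0.0``, which forces the random-effect
    variance to zero — the model reduces to an ordinary logistic GLM fit
    by iteratively reweighted least squares.  Mixed fits use a Laplace
    (posterior-mode) approximation with diffuse priors, whose
    standard errors closely track likelihood-based mixed-model software.

    Raises GlmmConvergenceError on optimizer failure and ValueError on a
    degenerate design (constant or duplicated feature columns).  Complete
    separation is detected heuristically (huge coefficients) and flagged
    in ``notes``.
    """
    import statsmodels.api as sm

    if isinstance(table, ObservationTable):
        df = table.contributing()
        fixation_index = table.fixation_index
    else:
        df = table
        fixation_index = None
    fixed = list(fixed)
    random = list(random)
    if re_variance is not None and re_variance == 0.0:
        random = []
    y = df["fixated"].to_numpy(dtype=float)
    X = df[fixed].to_numpy(dtype=float)
    _check_design(X, fixed)
    exog = np.column_stack([np.ones(len(df)), X])
    names = ["(intercept)"] + fixed
    notes: list[str] = []
    re_sd: dict[str, float] = {}

    if not random:
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise GlmmConvergenceError(str(exc)) from exc
        if not res.converged:
            raise GlmmConvergenceError("IRLS did not converge")
        est, se = np.asarray(res.params), np.asarray(res.bse)
        converged = True
    else:
        for g in random:
            if df[g].nunique() < 2:
                raise ValueError(f"random grouping {g!r} needs >= 2 levels")
        vc_mats = []
        vc_names = []
        ident = []
        for k, g in enumerate(random):
            levels = pd.Categorical(df[g])
            mat = np.zeros((len(df), len(levels.categories)))
            mat[np.arange(len(df)), levels.codes] = 1.0
            vc_mats.append(mat)
            vc_names += [f"{g}[{lv}]" for lv in levels.categories]
            ident += [k] * len(levels.categories)
        exog_vc = np.concatenate(vc_mats, axis=1)
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        model = BinomialBayesMixedGLM(
            y, exog, exog_vc, ident=np.asarray(ident),
            vcp_p=vcp_prior_sd, fe_p=fe_prior_sd,
            fep_names=names, vc_names=vc_names,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit_map()
        except Exception as exc:
            raise GlmmConvergenceError(str(exc)) from exc
        est, se = np.asarray(res.fe_mean), np.asarray(res.fe_sd)
        converged = True
        for k, g in enumerate(random):
            re_sd[g] = float(np.exp(res.vcp_mean[k]))

    if np.any(np.abs(est[1:]) > 15):
        notes.append("possible separation: |coefficient| > 15")
        logger.warning("fit_glmm: %s", notes[-1])
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"feature": names, "estimate": est, "se": se, "z": z, "p": p}
    )
    return GlmmResult(out, re_sd, fixation_index, len(df), converged, notes)


@dataclass
class WeightTable:
    """Fig.-style normalized factor weights across scanpath positions.

    ``weights``: rows = fixation index, columns = features; each row is
    clamp-at-zero z-statistics normalized to sum 1 (an all-nonpositive row
    falls back to uniform with a warning).  ``instances``: the proportion
    of (subject, image) pairs contributing at each index, normalized to
    sum 1 down the column.
    """

    weights: pd.DataFrame
    instances: pd.Series


def weight_table(
    results: Sequence[GlmmResult],
    instances: Sequence[int],
    features: Sequence[str] | None = None,
) -> WeightTable:
    """Summarize per-fixation-index GLMM fits as a normalized weight table.

    ``results`` holds one GlmmResult per fixation index (in order);
    ``instances`` the contributing-pair count at each index.  Negative
    z-statistics carry no positive evidence that a factor attracts gaze,
    so they clamp to zero before row normalization; raw z's remain
    available in the GlmmResults.
    """
    if len(results) != len(instances):
        raise ValueError("need one instance count per GlmmResult")
    if features is None:
        features = [f for f in results[0].table["feature"] if f != "(intercept)"]
    rows = []
    index = []
    for r in results:
        z = np.array([r.z(f) for f in features], dtype=float)
        w = np.clip(z, 0.0, None)
        if w.sum() == 0:
            logger.warning(
                "fixation %s: all z <= 0; uniform weight row", r.fixation_index
            )
            w = np.ones_like(w)
        rows.append(w / w.sum())
        index.append(r.fixation_index if r.fixation_index is not None else len(index) + 1)
    inst = np.asarray(instances, dtype=float)
    if inst.sum() == 0:
        raise ValueError("no contributing instances at any fixation index")
    weights = pd.DataFrame(rows, index=index, columns=list(features))
    weights.index.name = "fixation"
    return WeightTable(weights, pd.Series(inst / inst.sum(), index=index, name="instances"))


def results_to_frame(results: Sequence[GlmmResult]) -> pd.DataFrame:
    """Flatten GLMM fits into a long table (fixation, feature, estimate,
    SE, z, p, p_bonferroni), the layout used for reporting significance;
    the Bonferroni correction multiplies p by features x fixation
    indices."""
    frames = []
    for r in results:
        t = r.table[r.table["feature"] != "(intercept)"].copy()
        t.insert(0, "fixation", r.fixation_index)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
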