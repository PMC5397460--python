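"""Reader-study evaluation: confusion metrics, ordinal ROC/AUC, weighted kappa.

Lesions are rated on a four-point diagnostic confidence scale (1 definitely
benign, 2 possibly benign, 3 possibly malignant, 4 definitely malignant); a
score of 3 or 4 on a metastatic lesion counts as true positive and 1 or 2 on
a benign lesion as true negative.  The ROC curve over the four ordinal
operating points yields a tie-corrected rank AUC; inter-observer agreement on
the same scale is summarized by the weighted kappa statistic; the middle two
scores form the "equivocal" judgments whose rate the fusion display aims to
reduce.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

N_CATEGORIES = 4
SCORE_LABELS = {1: "definitely benign", 2: "possibly benign",
                3: "possibly malignant", 4: "definitely malignant"}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class OrdinalCounts:
    """Per-score lesion counts for one reader x one modality.

    ``malignant[k]`` / ``benign[k]`` is the number of metastatic / benign
    lesions given score k+1.
    """

    malignant: np.ndarray
    benign: np.ndarray

    def __post_init__(self) -> None:
        self.malignant = np.asarray(self.malignant, dtype=np.int64)
        self.benign = np.asarray(self.benign, dtype=np.int64)
        for arr in (self.malignant, self.benign):
            if arr.shape != (N_CATEGORIES,):
                raise ValueError(f"expected {N_CATEGORIES} score counts, got {arr.shape}")
            if np.any(arr < 0):
                raise ValueError("counts must be nonnegative")

    @property
    def n_malignant(self) -> int:
        return int(self.malignant.sum())

    @property
    def n_benign(self) -> int:
        return int(self.benign.sum())

    @property
    def n_total(self) -> int:
        return self.n_malignant + self.n_benign

    @classmethod
    def from_scores(cls, truth, scores) -> "OrdinalCounts":
        """Tally per-lesion scores; ``truth`` holds 'malignant'/'benign' or bools."""
        truth = np.asarray(truth)
        scores = np.asarray(scores, dtype=np.int64)
        if np.any((scores < 1) | (scores > N_CATEGORIES)):
            raise ValueError("scores must lie in 1..4")
        mal = truth == ("malignant" if truth.dtype.kind in "OUS" else True)
        return cls(
            malignant=np.bincount(scores[mal] - 1, minlength=N_CATEGORIES),
            benign=np.bincount(scores[~mal] - 1, minlength=N_CATEGORIES))


@dataclass
class ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV as exact percentages, with raw counts."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def rounded(self) -> dict:
        """Half-up integer percentages, the convention of clinical tables."""
        return {k: (round_half_up(v) if np.isfinite(v) else None)
                for k, v in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity),
                             ("ppv", self.ppv), ("npv", self.npv))}


def confusion_metrics(c: OrdinalCounts, cutoff: int = 3) -> ConfusionMetrics:
    """Dichotomize at ``score >= cutoff`` = test-positive and tabulate.

    Zero denominators yield NaN (flagged undefined) rather than an error.
    """
    tp = int(c.malignant[cutoff - 1:].sum())
    fn = int(c.malignant[:cutoff - 1].sum())
    fp = int(c.benign[cutoff - 1:].sum())
    tn = int(c.benign[:cutoff - 1].sum())

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return ConfusionMetrics(
        sensitivity=pct(tp, tp + fn), specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp), npv=pct(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class RocResult:
    """Tie-corrected AUC plus the empirical operating points (FPR, TPR)."""

    auc: float
    operating_points: np.ndarray  # (5, 2): cutoffs >=1 ... >=5

    def __float__(self) -> float:
        return self.auc


def empirical_auc(c: OrdinalCounts) -> RocResult:
    """Two-sample rank AUC over the ordinal scores, with tie correction.

    AUC = [sum_{i>j} m_i b_j + 1/2 sum_i m_i b_i] / (M B), the probability
    that a random metastatic lesion outscores a random benign one, ties
    counting half; identical to the trapezoidal area under the 5-point
    empirical ROC curve returned in ``operating_points``.
    """
    m, b = c.malignant.astype(float), c.benign.astype(float)
    M, B = m.sum(), b.sum()
    if M == 0 or B == 0:
        raise ValueError("empirical AUC undefined: one class is empty")
    b_below = np.concatenate(([0.0], np.cumsum(b)[:-1]))  # benign with lower score
    auc = float((m @ b_below + 0.5 * (m @ b)) / (M * B))
    # operating points at cutoffs k = 1..5 ("positive" means score >= k)
    pts = []
    for k in range(1, N_CATEGORIES + 2):
        tpr = m[k - 1:].sum() / M
        fpr = b[k - 1:].sum() / B
        pts.append((fpr, tpr))
    return RocResult(auc=auc, operating_points=np.array(pts))


def equivocal_summary(c: OrdinalCounts) -> tuple[int, int]:
    """Count of equivocal judgments (scores 2-3, both classes) and integer %."""
    count = int(c.malignant[1:3].sum() + c.benign[1:3].sum())
    pct = round_half_up(100.0 * count / c.n_total) if c.n_total else 0
    return count, pct


#: Agreement bands for interpreting kappa.
KAPPA_SCALE: tuple = (
    (0.0, 0.0, "poor agreement"),
    (0.0, 0.20, "slight agreement"),
    (0.20, 0.40, "fair agreement"),
    (0.40, 0.60, "moderate agreement"),
    (0.60, 0.80, "substantial agreement"),
    (0.80, 1.00, "almost perfect agreement"),
)


def kappa_band(kappa: float) -> str:
    if not np.isfinite(kappa):
        return "undefined"
    if kappa <= 0.0:
        return "poor agreement"
    for lo, hi, name in KAPPA_SCALE[1:]:
        if lo < kappa <= hi + 1e-12:
            return name
    return "almost perfect agreement"


@dataclass
class KappaResult:
    kappa: float
    band: str
    weights: str


def weighted_kappa(crosstab, weights: str = "linear") -> KappaResult:
    """Weighted kappa for a 4x4 reader-1 x reader-2 cross-tabulation.

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with disagreement weights
    w_ij = |i-j|/3 (linear, default) or its square (quadratic); E is the
    margin-product expectation.  Degenerate margins (all observations in one
    category for both readers) give NaN, flagged via band "undefined".
    """
    o = np.asarray(crosstab, dtype=np.float64)
    if o.shape != (N_CATEGORIES, N_CATEGORIES):
        raise ValueError(f"cross-tab must be 4x4, got {o.shape}")
    if o.sum() < 1:
        raise ValueError("cross-tab must contain at least one observation")
    n = o.sum()
    i, j = np.meshgrid(np.arange(N_CATEGORIES), np.arange(N_CATEGORIES), indexing="ij")
    w = np.abs(i - j) / (N_CATEGORIES - 1)
    if weights == "quadratic":
        w = w ** 2
    elif weights != "linear":
        raise ValueError(f"weights must be 'linear' or 'quadratic', got {weights!r}")
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    denom = (w * e).sum()
    if denom <= 0:
        return KappaResult(kappa=float("nan"), band="undefined", weights=weights)
    kappa = 1.0 - (w * o).sum() / denom
    return KappaResult(kappa=float(kappa), band=kappa_band(kappa), weights=weights)


def crosstab_from_scores(scores_r1, scores_r2) -> np.ndarray:
    """4x4 joint counts of two readers' scores over the same lesions."""
    s1 = np.asarray(scores_r1, dtype=np.int64)
    s2 = np.asarray(scores_r2, dtype=np.int64)
    if s1.shape != s2.shape:
        raise ValueError("readers must score the same lesions")
    out = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=np.int64)
    np.add.at(out, (s1 - 1, s2 - 1), 1)
    return out


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    p_adjusted: float
    flagged: bool = False


def paired_t_bonferroni(values_a, values_b, n_comparisons: int = 1) -> PairedTResult:
    """Paired Student t test with Bonferroni-adjusted two-sided p.

    Zero variance of the paired differences is flagged (t/p NaN) rather than
    raised; ``p_adjusted = min(1, p * n_comparisons)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    diffs = a - b
    df = len(a) - 1
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):  # identical samples: no difference at all
            return PairedTResult(t=0.0, df=df, p=1.0, p_adjusted=1.0)
        return PairedTResult(t=float("nan"), df=df, p=float("nan"),
                             p_adjusted=float("nan"), flagged=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(t=float(t), df=df, p=float(p),
                         p_adjusted=min(1.0, float(p) * n_comparisons))


def _auc_variance(c: OrdinalCounts, auc: float) -> float:
    """Placement-value (structural-component) variance of the rank AUC."""
    m, b = c.malignant.astype(float), c.benign.astype(float)
    M, B = m.sum(), b.sum()
    b_below = np.concatenate(([0.0], np.cumsum(b)[:-1]))
    m_above = np.cumsum(m[::-1])[::-1] - m  # malignant with strictly higher score
    v10 = (b_below + 0.5 * b) / B       # placement of each malignant score level
    v01 = (m_above + 0.5 * m) / M       # placement of each benign score level
    s10 = (m @ (v10 - auc) ** 2) / max(M - 1, 1)
    s01 = (b @ (v01 - auc) ** 2) / max(B - 1, 1)
    return float(s10 / M + s01 / B)


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    p: float
    method: str


def compare_auc(a, b, paired: bool = False, n_boot: int = 2000,
                seed: int = 0) -> AucComparison:
    """Compare two AUCs from ordinal score data.

    Unpaired: ``a``/``b`` are :class:`OrdinalCounts`; a normal test on the
    AUC difference with tie-corrected placement-value variances.  Paired:
    ``a``/``b`` are tidy per-lesion tables (columns ``truth`` and ``score``
    over the same lesions in the same order); a seeded bootstrap over lesions
    forms the null.  Counts-only input with paired=True is an input error:
    the pairing of lesions cannot be recovered from marginal counts.
    """
    if paired:
        if isinstance(a, OrdinalCounts) or isinstance(b, OrdinalCounts):
            raise ValueError("paired comparison needs per-lesion scores, not counts")
        ta, sa = np.asarray(a["truth"]), np.asarray(a["score"], dtype=int)
        tb, sb = np.asarray(b["truth"]), np.asarray(b["score"], dtype=int)
        if len(ta) != len(tb) or np.any(ta != tb):
            raise ValueError("paired tables must cover the same lesions in order")
        auc_a = empirical_auc(OrdinalCounts.from_scores(ta, sa)).auc
        auc_b = empirical_auc(OrdinalCounts.from_scores(tb, sb)).auc
        observed = auc_a - auc_b
        rng = np.random.default_rng(seed)
        n = len(ta)
        count = 0
        valid = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            t_i = ta[idx]
            if (t_i == t_i[0]).all():
                continue  # resample lost one class entirely
            d = (empirical_auc(OrdinalCounts.from_scores(t_i, sa[idx])).auc
                 - empirical_auc(OrdinalCounts.from_scores(t_i, sb[idx])).auc)
            valid += 1
            if abs(d - observed) >= abs(observed) - 1e-12:
                count += 1
        p = (count + 1) / (valid + 1) if valid else 1.0
        return AucComparison(auc_a=auc_a, auc_b=auc_b, p=min(1.0, float(p)),
                             method="bootstrap (paired, %d resamples)" % n_boot)

    ra, rb = empirical_auc(a), empirical_auc(b)
    var = _auc_variance(a, ra.auc) + _auc_variance(b, rb.auc)
    if var <= 0:
        p = 1.0 if np.isclose(ra.auc, rb.auc) else 0.0
    else:
        z = (ra.auc - rb.auc) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return AucComparison(auc_a=ra.auc, auc_b=rb.auc, p=float(min(1.0, p)),
                         method="normal approximation (unpaired)")


def scores_table_to_counts(df: pd.DataFrame) -> dict:
    """Group a tidy score table into OrdinalCounts per (reader, modality)."""
    required = {"truth", "reader", "modality", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table lacks columns: {sorted(missing)}")
    out = {}
    for (reader, modality), grp in df.groupby(["reader", "modality"]):
        out[(reader, modality)] = OrdinalCounts.from_scores(grp["truth"], grp["score"])
    return out
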