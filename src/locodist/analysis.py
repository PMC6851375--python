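"""Statistical harness on pairwise distance matrices.

Given a cohort with a binary condition label (control-like vs alarmed-like),
this module summarizes a distance matrix by pair category (within-A, mixed,
within-B), runs a randomized-partition (permutation) test of the observed
cross-partition mean distance against random equal splits of the cohort, and
fits a univariate logistic classifier on any per-subject feature (e.g. the
IIBDD) with the 0.5-probability decision rule.

p-values for the partition test are reported from the normal approximation of
the sampled null, 2*(1 - Phi(|z|)) — an empirical rank p cannot resolve the
tail beyond 1/n_samples — alongside the empirical rank itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ArgumentError
from .tracking_io import DistanceMatrix

__all__ = [
    "LabeledCohort",
    "PartitionTestResult",
    "LogisticFit",
    "group_summary",
    "randomized_partition_test",
    "p_from_z",
    "logistic_classify",
    "n_equal_splits",
]


@dataclass(frozen=True)
class LabeledCohort:
    """Subject labels with a binary class for each subject."""

    subjects: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self):
        if len(self.subjects) != len(self.classes):
            raise ArgumentError("one class per subject required")
        if len(set(self.subjects)) != len(self.subjects):
            raise ArgumentError("duplicate subject labels")
        if len(set(self.classes)) != 2:
            raise ArgumentError("exactly two classes required")

    @property
    def class_names(self) -> tuple[str, str]:
        # first-appearance order, deterministic
        seen: list[str] = []
        for c in self.classes:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def mask(self, cls: str) -> np.ndarray:
        return np.array([c == cls for c in self.classes])


def _aligned_mask(dmat: DistanceMatrix, cohort: LabeledCohort) -> np.ndarray:
    if set(dmat.labels) != set(cohort.subjects):
        raise ArgumentError("cohort subjects do not match distance-matrix labels")
    cls_of = dict(zip(cohort.subjects, cohort.classes))
    a = cohort.class_names[0]
    return np.array([cls_of[s] == a for s in dmat.labels])


def group_summary(dmat: DistanceMatrix, cohort: LabeledCohort) -> dict:
    """Mean and sd of pair distances per category: within-A, mixed, within-B.

    Unordered pairs only; sds are population sds of the category's pair
    values.  Also reports the overall (all-pairs) summary.
    """
    is_a = _aligned_mask(dmat, cohort)
    n = len(dmat.labels)
    iu, ju = np.triu_indices(n, k=1)
    vals = dmat.values[iu, ju]
    cat_a = is_a[iu] & is_a[ju]
    cat_b = ~is_a[iu] & ~is_a[ju]
    cat_mixed = ~cat_a & ~cat_b
    name_a, name_b = cohort.class_names
    out = {}
    for name, mask in [
        (f"{name_a}-{name_a}", cat_a),
        (f"{name_a}-{name_b}", cat_mixed),
        (f"{name_b}-{name_b}", cat_b),
        ("all", np.ones_like(cat_a)),
    ]:
        v = vals[mask]
        out[name] = {
            "n_pairs": int(mask.sum()),
            "mean": float(np.mean(v)) if len(v) else float("nan"),
            "sd": float(np.std(v)) if len(v) else float("nan"),
        }
    return out


def p_from_z(z: float) -> float:
    """Two-sided standard normal tail probability 2*(1 - Phi(|z|))."""
    if not math.isfinite(z):
        raise ArgumentError("z must be finite")
    return float(2.0 * norm.sf(abs(z)))


def n_equal_splits(n_subjects: int) -> int:
    """Number of ways to divide ``n_subjects`` into two equal halves, C(n, n/2)."""
    if n_subjects % 2:
        raise ArgumentError("equal split needs an even cohort")
    return math.comb(n_subjects, n_subjects // 2)


@dataclass
class PartitionTestResult:
    """Randomized-partition test of the observed cross-class mean distance."""

    observed_mean: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float
    n_samples: int
    seed: int | None
    degenerate: bool = False


def randomized_partition_test(
    dmat: DistanceMatrix,
    cohort: LabeledCohort,
    n_samples: int = 100_000,
    seed: int | None = None,
    allow_unequal: bool = False,
) -> PartitionTestResult:
    """Compare the observed cross-class mean distance to random equal splits.

    Samples ``n_samples`` uniform divisions of the cohort into two halves of
    the observed class sizes (with replacement across samples; collisions are
    negligible against the C(n, n/2) split space), computes the mean
    cross-subset distance for each, and reports the standard score of the
    observed cross-class mean against that null along with the two-sided
    normal-tail p-value and the empirical rank p.
    """
    if n_samples < 1000:
        raise ArgumentError("use at least 1000 null samples")
    is_a = _aligned_mask(dmat, cohort)
    n_a = int(is_a.sum())
    n = len(dmat.labels)
    if not allow_unequal and 2 * n_a != n:
        raise ArgumentError("class sizes differ; pass allow_unequal=True to proceed")
    d = dmat.values
    observed = float(np.mean(d[np.ix_(is_a, ~is_a)]))

    rng = np.random.default_rng(seed)
    null = np.empty(n_samples)
    idx = np.arange(n)
    # vectorized in blocks: argsort of uniforms gives uniform random subsets
    block = 2000
    done = 0
    while done < n_samples:
        b = min(block, n_samples - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        left = order[:, :n_a]
        right = order[:, n_a:]
        # mean cross distance for each sampled split
        sub = d[left[:, :, None], right[:, None, :]]
        null[done : done + b] = sub.mean(axis=(1, 2))
        done += b
    null_mean = float(null.mean())
    null_sd = float(null.std())
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
        return PartitionTestResult(
            observed, null_mean, 0.0, 0.0, 1.0, 1.0, n_samples, seed, degenerate=True
        )
    z = (observed - null_mean) / null_sd
    p_emp = float(
        (np.sum(np.abs(null - null_mean) >= abs(observed - null_mean)) + 1)
        / (n_samples + 1)
    )
    return PartitionTestResult(observed, null_mean, null_sd, float(z), p_from_z(z), p_emp, n_samples, seed)


@dataclass
class LogisticFit:
    """Univariate logistic classifier fit by IRLS, with the 0.5 decision rule."""

    intercept: float
    slope: float
    chi2: float                  # likelihood-ratio vs intercept-only
    p: float
    probabilities: np.ndarray    # per-subject P(class B)
    predicted: tuple[str, ...]
    accuracy: float
    loglik_trace: list[float] = field(default_factory=list)
    separated: bool = False
    classes: tuple[str, str] = ("A", "B")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood with logit link
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_classify(
    feature: np.ndarray,
    cohort: LabeledCohort,
    max_iter: int = 50,
    tol: float = 1e-10,
    coef_cap: float = 500.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of class on one feature.

    Fits intercept + slope by iteratively reweighted least squares; the
    per-iteration log-likelihood trace is recorded (and is non-decreasing —
    steps are halved when they would decrease it).  Complete separation is
    flagged when coefficients run away; they are capped and the 0.5-threshold
    classification is still reported.  The second class (by first appearance)
    is coded 1.
    """
    x = np.asarray(feature, dtype=float)
    if len(x) != len(cohort.subjects):
        raise ArgumentError("one feature value per subject required")
    if not np.all(np.isfinite(x)):
        raise ArgumentError("feature must be finite")
    name_a, name_b = cohort.class_names
    y = (~cohort.mask(name_a)).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ArgumentError("need at least 2 subjects per class")

    X = np.column_stack([np.ones_like(x), x])
    if np.ptp(x) == 0.0:
        # constant feature: intercept-only model, probabilities = prevalence
        p0 = float(y.mean())
        beta = np.array([np.log(p0 / (1.0 - p0)), 0.0])
        prob = np.full_like(x, p0)
        predicted = tuple(name_b if p > 0.5 else name_a for p in prob)
        truth = tuple(cohort.classes)
        return LogisticFit(
            intercept=float(beta[0]),
            slope=0.0,
            chi2=0.0,
            p=1.0,
            probabilities=prob,
            predicted=predicted,
            accuracy=float(np.mean([p == t for p, t in zip(predicted, truth)])),
            loglik_trace=[_loglik(y, X @ beta)],
            separated=False,
            classes=(name_a, name_b),
        )
    beta = np.zeros(2)
    ll = _loglik(y, X @ beta)
    trace = [ll]
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        # IRLS step = Newton step on the log-likelihood
        try:
            step = np.linalg.solve((X.T * w) @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        # halve the step until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_new = _loglik(y, X @ beta)
        trace.append(ll_new)
        if np.max(np.abs(np.asarray(beta))) > coef_cap:
            separated = True
            beta = np.clip(beta, -coef_cap, coef_cap)
            break
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new

    eta = X @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    # complete separation also shows as fitted probabilities saturating at
    # the observed classes even when the coefficients are still finite
    if np.all(np.abs(y - prob) < 1e-4):
        separated = True
    # intercept-only null for the likelihood-ratio chi^2
    p0 = float(y.mean())
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
    chi2 = max(2.0 * (_loglik(y, eta) - ll0), 0.0)
    from scipy.stats import chi2 as chi2_dist

    p_val = float(chi2_dist.sf(chi2, df=1))
    predicted = tuple(name_b if p > 0.5 else name_a for p in prob)
    truth = tuple(cohort.classes)
    accuracy = float(np.mean([p == t for p, t in zip(predicted, truth)]))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        chi2=float(chi2),
        p=p_val,
        probabilities=prob,
        predicted=predicted,
        accuracy=accuracy,
        loglik_trace=trace,
        separated=separated,
        classes=(name_a, name_b),
    )
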