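"""Out-of-sample evaluation: leave-3-out CV, permutation null, network screen.

Each network's predictor block is evaluated by repeatedly reserving three
participants, fitting a PLSR model on the rest, and scoring the mean square
error of the predicted versus observed (transformed) improvement on the
held-out three. When the number of 3-subject combinations C(n, 3) is within
the repetition cap, every combination is used exactly once (exhaustive
enumeration); otherwise a capped number of distinct combinations is sampled
without replacement. A permutation null repeats the procedure with the
outcome-to-subject pairing shuffled within the training set only, so null
models are always tested against real, unpermuted held-out data. A network
is reported as predictive when the real-versus-null error separation
reaches a medium Cohen's d (> 0.50) with a significant one-sided comparison
of the two error distributions; an add-one-smoothed empirical tail
probability is reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as _stats

from .normalization import BoxCoxTransformer
from .parcellation import UNASSIGNED, Parcellation, ThicknessMatrix, network_block
from .pls import PLSRegressor, _pls_fit_core

__all__ = [
    "SplitPlan",
    "EvalDistributions",
    "NetworkReport",
    "plan_splits",
    "cv_real",
    "cv_null",
    "effect_size",
    "empirical_p",
    "comparison_p",
    "pooled_r2",
    "screen_networks",
]


@dataclass(frozen=True)
class SplitPlan:
    """A set of held-out index triples for leave-``holdout_size``-out CV."""

    n_subjects: int
    holdout_size: int
    splits: tuple[tuple[int, ...], ...]
    exhaustive: bool
    n_requested: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in self.splits:
            if len(set(s)) != self.holdout_size or max(s) >= self.n_subjects:
                raise ValueError(f"invalid split {s}")


def _unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """The ``rank``-th k-combination of range(n) in lexicographic order."""
    out = []
    x = 0
    for i in range(k, 0, -1):
        while comb(n - x - 1, i - 1) <= rank:
            rank -= comb(n - x - 1, i - 1)
            x += 1
        out.append(x)
        x += 1
    return tuple(out)


def plan_splits(
    n: int, holdout: int = 3, cap: int = 10_000, seed: int | None = None
) -> SplitPlan:
    """Enumerate or sample distinct held-out triples.

    If C(n, holdout) <= cap the plan is exhaustive, in lexicographic order;
    otherwise ``cap`` distinct combinations are sampled without replacement
    using ``seed``.
    """
    if holdout < 1:
        raise ValueError("holdout must be >= 1")
    if n < holdout + 1:
        raise ValueError(f"need at least {holdout + 1} subjects, got {n}")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    total = comb(n, holdout)
    if total <= cap:
        splits = tuple(itertools.combinations(range(n), holdout))
        return SplitPlan(n, holdout, splits, True, total, seed)
    rng = np.random.default_rng(seed)
    ranks = rng.choice(total, size=cap, replace=False)
    splits = tuple(_unrank_combination(int(r), n, holdout) for r in ranks)
    return SplitPlan(n, holdout, splits, False, cap, seed)


@dataclass
class EvalDistributions:
    """Per-split (real) or per-repetition (null) out-of-sample MSEs."""

    mses: np.ndarray
    pooled_predictions: np.ndarray | None = None
    holdout_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mses = np.asarray(self.mses, dtype=float)
        if np.any(self.mses < 0):
            raise ValueError("negative MSE")


def _split_mse(X, y, test_idx, k, train_perm=None):
    """Fit PLSR on the complement of ``test_idx`` and return (mse, predictions).

    ``train_perm`` optionally permutes the training outcome against the
    training predictors (the permutation-null device); held-out data are
    never permuted.
    """
    n = X.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[list(test_idx)] = False
    Xtr = X[mask]
    ytr = y[mask]
    if train_perm is not None:
        ytr = ytr[train_perm]
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    _, _, _, _, coef, _ = _pls_fit_core(Xtr - xm, ytr - ym, k)
    pred = ym + (X[list(test_idx)] - xm) @ coef
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError(
            f"non-finite prediction for held-out subjects {tuple(test_idx)}"
        )
    return float(np.mean((pred - y[list(test_idx)]) ** 2)), pred


def cv_real(X, y, plan: SplitPlan, k: int = 4) -> EvalDistributions:
    """Real-side CV: per split, fit on the training rows, MSE on the held-out 3.

    Each subject's held-out predictions are also pooled (averaged over the
    splits holding it out) so an out-of-sample R-squared can be computed
    against the observed outcome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y) or X.shape[0] != plan.n_subjects:
        raise ValueError("X, y and plan sizes are inconsistent")
    min_train = plan.n_subjects - plan.holdout_size
    if min_train < k + 1:
        raise ValueError(
            f"training sets of {min_train} rows cannot support {k} components"
        )
    n = plan.n_subjects
    mses = np.empty(len(plan.splits))
    sums = np.zeros(n)
    counts = np.zeros(n)
    for i, test_idx in enumerate(plan.splits):
        mse, pred = _split_mse(X, y, test_idx, k)
        mses[i] = mse
        idx = list(test_idx)
        sums[idx] += pred
        counts[idx] += 1
    pooled = np.divide(sums, counts, out=np.full(n, np.nan), where=counts > 0)
    return EvalDistributions(mses, pooled, counts)


def cv_null(
    X,
    y,
    n_null: int = 10_000,
    k: int = 4,
    seed: int | None = None,
    holdout: int = 3,
) -> EvalDistributions:
    """Permutation-null CV distribution of out-of-sample MSE.

    Per repetition: draw one random ``holdout``-out split, permute the
    outcome-to-subject pairing within the training rows only, fit, and
    score against the *unpermuted* held-out outcome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n != len(y):
        raise ValueError("X and y sizes differ")
    if n - holdout < k + 1:
        raise ValueError(
            f"training sets of {n - holdout} rows cannot support {k} components"
        )
    rng = np.random.default_rng(seed)
    n_train = n - holdout
    mses = np.empty(n_null)
    for i in range(n_null):
        test_idx = rng.choice(n, size=holdout, replace=False)
        perm = rng.permutation(n_train)
        mses[i], _ = _split_mse(X, y, tuple(test_idx), k, train_perm=perm)
    return EvalDistributions(mses)


def effect_size(real_mses, null_mses) -> float:
    """Cohen's d between null and real MSE distributions.

    ``d = (mean(null) - mean(real)) / pooled SD`` with (n-1)-weighted
    pooling; positive when real models predict better (lower error).
    """
    a = np.asarray(real_mses, dtype=float)
    b = np.asarray(null_mses, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty MSE list")
    na, nb = a.size, b.size
    if na + nb < 3:
        raise ValueError("too few values to pool a standard deviation")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation; effect size undefined")
    return float((b.mean() - a.mean()) / np.sqrt(pooled_var))


def empirical_p(real_mses, null_mses) -> float:
    """One-sided empirical p with add-one smoothing.

    ``p = (1 + #{null MSE <= mean(real MSE)}) / (1 + n_null)``: the
    probability that chance-trained models predict held-out data at least
    as well as the real models do on average.
    """
    a = np.asarray(real_mses, dtype=float)
    b = np.asarray(null_mses, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty MSE list")
    return float((1 + np.sum(b <= a.mean())) / (1 + b.size))


def comparison_p(real_mses, null_mses) -> float:
    """One-sided p for real models outpredicting chance-trained models.

    Welch two-sample t-test that the real MSE distribution has a lower
    mean than the permutation-null MSE distribution. This is the screen's
    default significance: it compares the two out-of-sample error
    distributions directly, which is sensitive at the sample sizes the
    evaluation produces (thousands of splits/repetitions) even though any
    single 3-subject split MSE is highly dispersed. The empirical tail
    probability (:func:`empirical_p`) is reported alongside.
    """
    a = np.asarray(real_mses, dtype=float)
    b = np.asarray(null_mses, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 MSEs per side")
    res = _stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.pvalue)


def pooled_r2(dist: EvalDistributions, y) -> float:
    """Squared Pearson correlation of pooled held-out predictions vs observed."""
    if dist.pooled_predictions is None:
        raise ValueError("distribution has no pooled predictions")
    pred = dist.pooled_predictions
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(pred)
    if ok.sum() < 3:
        raise ValueError("too few pooled predictions for a correlation")
    if np.std(pred[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan")
    r = np.corrcoef(pred[ok], y[ok])[0, 1]
    return float(r * r)


@dataclass
class NetworkReport:
    """Out-of-sample result for one network's predictor block."""

    network: str
    effect_size: float = float("nan")
    p_value: float = float("nan")
    p_empirical: float = float("nan")
    oos_r2: float = float("nan")
    first_score_r2: float = float("nan")
    n_splits: int = 0
    n_null: int = 0
    passed_screen: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "effect_size": self.effect_size,
            "p_value": self.p_value,
            "p_empirical": self.p_empirical,
            "oos_r2": self.oos_r2,
            "first_score_r2": self.first_score_r2,
            "n_splits": self.n_splits,
            "n_null": self.n_null,
            "passed_screen": self.passed_screen,
            "error": self.error,
        }


def screen_networks(
    thickness: ThicknessMatrix,
    parcellation: Parcellation,
    y,
    *,
    n_components: int = 4,
    holdout: int = 3,
    cap: int = 10_000,
    n_null: int = 10_000,
    alpha: float = 0.001,
    es_threshold: float = 0.50,
    seed: int | None = None,
    networks: list[str] | None = None,
    include_unassigned: bool = False,
    boxcox_per_fold: bool = False,
) -> list[NetworkReport]:
    """Run the full real-versus-null evaluation for each network.

    The improvement outcome ``y`` (percent) is Box-Cox normalized once on
    the modeling sample (the transform is frozen before cross-validation;
    ``boxcox_per_fold=True`` instead refits it inside every training fold).
    Each network's ROI block is then evaluated by :func:`cv_real` /
    :func:`cv_null`, and the report rows are ordered by descending effect
    size. A per-network failure is returned as a flagged row, never raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    if thickness.n_subjects != len(y):
        raise ValueError("thickness and outcome are not aligned")
    if thickness.n_subjects < holdout + 1:
        raise ValueError(f"need at least {holdout + 1} subjects")
    if networks is None:
        networks = [
            n
            for n in parcellation.networks
            if include_unassigned or n != UNASSIGNED
        ]
    transform = BoxCoxTransformer().fit(y)
    yt = transform.transform(y)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(networks))
    reports: list[NetworkReport] = []
    for i, network in enumerate(networks):
        report = NetworkReport(network=network)
        try:
            X = network_block(thickness, parcellation, network)
            plan_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
            null_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
            plan = plan_splits(len(y), holdout, cap, plan_seed)
            if boxcox_per_fold:
                real = _cv_real_per_fold_transform(X, y, plan, n_components)
                null = _cv_null_per_fold_transform(
                    X, y, n_null, n_components, null_seed, holdout
                )
            else:
                real = cv_real(X, yt, plan, n_components)
                null = cv_null(X, yt, n_null, n_components, null_seed, holdout)
            report.n_splits = len(plan.splits)
            report.n_null = n_null
            report.effect_size = effect_size(real.mses, null.mses)
            report.p_value = comparison_p(real.mses, null.mses)
            report.p_empirical = empirical_p(real.mses, null.mses)
            if real.pooled_predictions is not None:
                report.oos_r2 = pooled_r2(real, yt)
            model = PLSRegressor(n_components=n_components).fit(X, yt)
            report.first_score_r2 = model.first_score_r2(X, yt)
            report.passed_screen = (
                report.effect_size > es_threshold and report.p_value < alpha
            )
        except Exception as exc:  # surface, never abort the whole screen
            report.error = f"{type(exc).__name__}: {exc}"
        reports.append(report)
    reports.sort(
        key=lambda r: (r.error is not None, -(r.effect_size if np.isfinite(r.effect_size) else -np.inf))
    )
    return reports


def _fold_transformed_mse(X, y, test_idx, k, rng_perm=None):
    n = X.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[list(test_idx)] = False
    tr = BoxCoxTransformer().fit(y[mask])
    yt = tr.transform(y)
    perm = None if rng_perm is None else rng_perm
    mse, _ = _split_mse(X, yt, test_idx, k, train_perm=perm)
    return mse


def _cv_real_per_fold_transform(X, y, plan, k):
    mses = np.array(
        [_fold_transformed_mse(X, y, t, k) for t in plan.splits]
    )
    return EvalDistributions(mses)


def _cv_null_per_fold_transform(X, y, n_null, k, seed, holdout):
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    mses = np.empty(n_null)
    for i in range(n_null):
        test_idx = tuple(rng.choice(n, size=holdout, replace=False))
        perm = rng.permutation(n - holdout)
        mses[i] = _fold_transformed_mse(X, y, test_idx, k, rng_perm=perm)
    return EvalDistributions(mses)
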