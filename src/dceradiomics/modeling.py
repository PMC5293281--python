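"""Feature selection and multi-class classification.

The classifier is a one-against-others (one-vs-rest) bank of binary
logistic-regression models with a small ridge term, fitted by iteratively
reweighted least squares; per-class probabilities are normalized to sum 1.

Feature selection is a two-stage wrapper scheme:

* a generational genetic algorithm over 90-bit inclusion chromosomes
  (:func:`ea_search`), whose fitness is the prevalence-weighted mean
  one-vs-rest AUC of the classifier under stratified k-fold
  cross-validation, establishes an optimal feature pool;
* inside leave-one-out cross-validation (:func:`loocv_evaluate`), greedy
  forward wrapper selection over that pool picks the per-fold subset, and
  held-out class probabilities accumulate into per-class ROC/AUC estimates
  (DeLong confidence intervals), best-threshold operating points and a
  per-feature selection-frequency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core_io import FeatureTable, PipelineConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# One-vs-rest ridge logistic regression (IRLS)


def _fit_binary_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 12, balanced: bool = True
) -> np.ndarray:
    """Newton/IRLS fit of P(y=1|x) = sigmoid(b0 + x.w) with ridge on w.

    Returns the coefficient vector [b0, w...]. The ridge term keeps the
    Hessian invertible under separation; the linear predictor is clipped to
    +-30 to avoid overflow at near-separation. Twelve Newton iterations
    settle any non-separable fit to well below the probability tolerances
    that matter for ranking; under separation further iterations only
    inflate the coefficient norm.

    ``balanced`` weights observations so both classes carry equal total
    weight. Under leave-one-out, removing one case shifts the training
    prevalence of its own class; an unweighted one-vs-rest intercept then
    systematically anti-ranks the held-out class (driving null AUCs far
    below 0.5). Balancing pins the intercept to the 50/50 operating point
    and removes the artifact without touching the slopes' ranking role.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    if balanced:
        n1 = max(y.sum(), 1.0)
        n0 = max(n - y.sum(), 1.0)
        wobs = np.where(y == 1, 0.5 * n / n1, 0.5 * n / n0)
    else:
        wobs = np.ones(n)
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (wobs * (y - mu)) - pen * beta
        w = np.maximum(wobs * mu * (1.0 - mu), 1e-10)
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


@dataclass
class MulticlassLogistic:
    """One binary ridge-logistic model per class versus the rest."""

    classes: tuple[str, ...]
    coefs: dict[str, np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kept: np.ndarray  # columns with nonzero training sd
    priors: dict[str, float]
    degenerate_classes: tuple[str, ...] = ()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        Z = (X[:, self.kept] - self.feature_mean) / self.feature_sd
        Zd = np.column_stack([np.ones(len(Z)), Z])
        raw = np.empty((len(Z), len(self.classes)))
        for ci, cls in enumerate(self.classes):
            beta = self.coefs[cls]
            if beta is None:
                raw[:, ci] = self.priors[cls]
            else:
                eta = np.clip(Zd @ beta, -30, 30)
                raw[:, ci] = 1.0 / (1.0 + np.exp(-eta))
        total = raw.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return raw / total


def train_multiclass_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-8, classes: tuple[str, ...] | None = None
) -> MulticlassLogistic:
    """Fit the one-against-others classifier.

    Features are standardized to the training fold (zero-sd columns are
    dropped for that fit). A class with fewer than 2 training cases gets a
    flagged degenerate model that predicts its training prevalence.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if classes is None:
        classes = tuple(sorted(set(y.tolist())))
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least 2 classes present for training")
    sd = X.std(axis=0)
    kept = sd > 0
    mean = X[:, kept].mean(axis=0) if kept.any() else np.empty(0)
    sdk = sd[kept] if kept.any() else np.empty(0)
    Z = (X[:, kept] - mean) / sdk if kept.any() else np.empty((len(X), 0))

    coefs: dict[str, np.ndarray] = {}
    priors: dict[str, float] = {}
    degenerate: list[str] = []
    n = len(y)
    for cls in classes:
        yb = (y == cls).astype(np.float64)
        priors[cls] = float(yb.mean()) if n else 0.0
        if yb.sum() < 2 or (n - yb.sum()) < 1:
            degenerate.append(cls)
            coefs[cls] = None
            continue
        coefs[cls] = _fit_binary_logistic(Z, yb, ridge)
    if degenerate:
        log.warning("degenerate one-vs-rest models for classes %s", degenerate)
    return MulticlassLogistic(
        classes=classes, coefs=coefs, feature_mean=mean, feature_sd=sdk,
        kept=kept, priors=priors, degenerate_classes=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery


@dataclass(frozen=True)
class AucEstimate:
    """AUC with a 95% DeLong confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    se: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def roc_auc(scores, labels) -> AucEstimate:
    """AUC by the Mann-Whitney identity (ties counted half) with a DeLong
    95% confidence interval truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label values must be present")
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = int(labels.sum()), int((~labels).sum())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = 1.959963984540054
    return AucEstimate(auc=auc, ci_low=max(0.0, auc - z * se), ci_high=min(1.0, auc + z * se), se=se)


def overall_auc(per_class: dict[str, AucEstimate], class_counts: dict[str, int]) -> tuple[float, float]:
    """(prevalence-weighted mean, unweighted mean) of one-vs-rest AUCs."""
    classes = list(per_class)
    aucs = np.array([per_class[c].auc for c in classes])
    counts = np.array([class_counts[c] for c in classes], dtype=np.float64)
    return float((aucs * counts).sum() / counts.sum()), float(aucs.mean())


def compare_auc_paired(scores_a, scores_b, labels) -> float:
    """Two-sided paired DeLong test for a difference of correlated AUCs."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score vectors and labels must cover the same cases")
    if np.array_equal(scores_a, scores_b):
        return 1.0
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    v10 = np.stack([v10_a, v10_b])
    v01 = np.stack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        # degenerate variance: identical rankings -> no evidence of a
        # difference; different AUCs with zero estimated variance -> the
        # statistic diverges
        return 1.0 if auc_a == auc_b else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def best_threshold(scores, labels) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing their average.

    The rule classifies ``score >= threshold`` as positive. Candidates are
    the midpoints between adjacent sorted unique scores plus the extremes;
    ties prefer the lower threshold. With all scores equal the chosen cut is
    that value itself (everything positive: sensitivity 1, specificity 0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    uniq = np.unique(scores)
    candidates = [uniq[0]] if len(uniq) == 1 else list((uniq[:-1] + uniq[1:]) / 2.0) + [uniq[-1] + 1.0, uniq[0]]
    candidates = sorted(candidates)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for t in candidates:
        pred = scores >= t
        sens = (pred & labels).sum() / n_pos if n_pos else 0.0
        spec = (~pred & ~labels).sum() / n_neg if n_neg else 0.0
        key = (-(sens + spec) / 2.0, t)
        if best is None or key < best[0]:
            best = (key, (float(t), float(sens), float(spec)))
    return best[1]


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value across groups.

    All-identical values return (0, 1) instead of raising.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.unique(values).size == 1:
        return 0.0, 1.0
    samples = [values[groups == g] for g in uniq]
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Cross-validated fitness of a feature subset


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays of k folds with per-class round-robin assignment."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, case in enumerate(idx):
            folds[i % k].append(int(case))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cv_probabilities(X: np.ndarray, y: np.ndarray, k: int, ridge: float, fold_seed: int) -> np.ndarray:
    """Out-of-fold class probabilities under stratified k-fold CV."""
    classes = tuple(sorted(set(y.tolist())))
    rng = np.random.default_rng(fold_seed)
    folds = _stratified_folds(y, k, rng)
    probs = np.zeros((len(y), len(classes)))
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        model = train_multiclass_logistic(X[train_idx], y[train_idx], ridge=ridge, classes=classes)
        probs[test_idx] = model.predict_proba(X[test_idx])
    return probs


def _overall_auc_from_probs(probs: np.ndarray, y: np.ndarray, classes: tuple[str, ...]) -> float:
    aucs = {}
    counts = {}
    for ci, cls in enumerate(classes):
        lab = y == cls
        if lab.all() or not lab.any():
            continue
        aucs[cls] = roc_auc(probs[:, ci], lab)
        counts[cls] = int(lab.sum())
    if not aucs:
        return 0.5
    return overall_auc(aucs, counts)[0]


def subset_fitness(X: np.ndarray, y: np.ndarray, columns: np.ndarray, k: int, ridge: float, fold_seed: int) -> float:
    """Prevalence-weighted one-vs-rest AUC of the classifier restricted to
    ``columns``, from stratified k-fold out-of-fold probabilities. An empty
    subset scores 0.5 (prior-only model)."""
    classes = tuple(sorted(set(y.tolist())))
    if len(columns) == 0:
        return 0.5
    probs = cv_probabilities(X[:, columns], y, k, ridge, fold_seed)
    return _overall_auc_from_probs(probs, y, classes)


def training_fitness(X: np.ndarray, y: np.ndarray, columns: np.ndarray, ridge: float) -> float:
    """Training-set overall AUC of the classifier on ``columns`` (optimistic:
    no held-out data; offered as a cheaper alternative fitness)."""
    classes = tuple(sorted(set(y.tolist())))
    if len(columns) == 0:
        return 0.5
    model = train_multiclass_logistic(X[:, columns], y, ridge=ridge, classes=classes)
    return _overall_auc_from_probs(model.predict_proba(X[:, columns]), y, classes)


# ---------------------------------------------------------------------------
# Evolutionary (genetic-algorithm) feature-subset search


@dataclass
class EAConfig:
    """Genetic-algorithm settings for feature-subset search.

    The study-scale defaults are population 500, 200 generations, per-bit
    mutation probability 0.01 and crossover probability 0.6.
    """

    population: int = 500
    generations: int = 200
    p_mutation: float = 0.01
    p_crossover: float = 0.6
    rng_seed: int = 0
    fitness_folds: int = 5
    stagnation: int = 20
    ridge: float = 1e-8
    #: per-bit inclusion probability of the initial population; sparse
    #: initialization suits wrapper selection (small subsets generalize
    #: better at these sample sizes and are cheaper to score)
    p_init: float = 0.1
    #: "cv" scores a subset by stratified k-fold out-of-fold AUC (default);
    #: "train" scores by training-set AUC, which overfits but is cheaper
    fitness_mode: str = "cv"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_crossover <= 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_pipeline(cls, cfg: PipelineConfig) -> "EAConfig":
        return cls(
            population=cfg.ea_population, generations=cfg.ea_generations,
            p_mutation=cfg.ea_p_mutation, p_crossover=cfg.ea_p_crossover,
            rng_seed=cfg.seed, fitness_folds=cfg.ea_fitness_folds,
            stagnation=cfg.ea_stagnation, ridge=cfg.ridge,
            fitness_mode=cfg.ea_fitness_mode,
        )


@dataclass
class Chromosome:
    """A binary feature-inclusion mask with its cross-validated AUC fitness."""

    bits: np.ndarray
    fitness: float

    @property
    def feature_indices(self) -> tuple[int, ...]:
        """Selected features as 1-based schema indices."""
        return tuple(int(i) + 1 for i in np.flatnonzero(self.bits))


def ea_search(table: FeatureTable, config: EAConfig | None = None) -> tuple[Chromosome, list[float]]:
    """Generational GA over feature-inclusion chromosomes.

    Tournament selection (size 2), single-point crossover, independent
    per-bit mutation, elitism of one; stops at the generation cap or after
    ``stagnation`` generations without improvement. Fitness is the
    cross-validated overall AUC of the one-vs-rest classifier on the
    selected columns; deterministic given ``rng_seed``.
    Returns the best chromosome and the per-generation best-fitness trace.
    """
    cfg = config or EAConfig()
    X = table.matrix
    y = np.asarray(table.labels)
    n, p = X.shape
    if n < 8 or len(set(table.labels)) < 2:
        raise ValueError("need at least 8 cases spanning at least 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0xEA]))
    fold_seed = int(rng.integers(2**31))
    cache: dict[bytes, float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cols = np.flatnonzero(bits)
            if cfg.fitness_mode == "train":
                cache[key] = training_fitness(X, y, cols, cfg.ridge)
            else:
                cache[key] = subset_fitness(X, y, cols, cfg.fitness_folds, cfg.ridge, fold_seed)
        return cache[key]

    def repair(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits[rng.integers(p)] = True
        return bits

    pop = [repair(rng.random(p) < cfg.p_init) for _ in range(cfg.population)]
    fits = np.array([fitness(b) for b in pop])
    trace: list[float] = [float(fits.max())]
    best_idx = int(np.argmax(fits))
    best = Chromosome(bits=pop[best_idx].copy(), fitness=float(fits[best_idx]))
    stagnant = 0
    for _ in range(1, cfg.generations):
        children: list[np.ndarray] = [best.bits.copy()]  # elitism of 1
        while len(children) < cfg.population:
            pa = _tournament(pop, fits, rng)
            pb = _tournament(pop, fits, rng)
            if rng.random() < cfg.p_crossover and p > 1:
                cut = int(rng.integers(1, p))
                ca = np.concatenate([pa[:cut], pb[cut:]])
                cb = np.concatenate([pb[:cut], pa[cut:]])
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                flip = rng.random(p) < cfg.p_mutation
                child ^= flip
                children.append(repair(child))
                if len(children) >= cfg.population:
                    break
        pop = children
        fits = np.array([fitness(b) for b in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = Chromosome(bits=pop[gen_best].copy(), fitness=float(fits[gen_best]))
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best.fitness)
        if stagnant >= cfg.stagnation:
            break
    return best, trace


def _tournament(pop: list[np.ndarray], fits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    i, j = rng.integers(len(pop), size=2)
    return pop[i] if fits[i] >= fits[j] else pop[j]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation with inner wrapper selection


@dataclass
class CvReport:
    """Held-out LOOCV results: probabilities, selections, ROC summaries."""

    classes: tuple[str, ...]
    per_case_probabilities: np.ndarray  # (n_cases, n_classes), rows sum to 1
    labels: list[str]
    per_fold_selected: list[tuple[int, ...]]  # 1-based feature indices per fold
    selection_frequency: dict[int, float]  # 1-based index -> fraction of folds
    per_class_auc: dict[str, AucEstimate]
    overall_auc_weighted: float
    overall_auc_unweighted: float
    operating_points: dict[str, tuple[float, float, float]]  # thr, sens, spec
    flagged_folds: tuple[int, ...] = ()

    def selection_table(self) -> list[tuple[int, float]]:
        """(feature index, frequency) sorted by frequency descending, then
        feature index ascending — the layout of a selection-frequency table."""
        return sorted(self.selection_frequency.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "labels": list(self.labels),
            "per_case_probabilities": self.per_case_probabilities.tolist(),
            "per_fold_selected": [list(s) for s in self.per_fold_selected],
            "selection_frequency": {str(k): v for k, v in self.selection_frequency.items()},
            "per_class_auc": {
                c: {"auc": e.auc, "ci_low": e.ci_low, "ci_high": e.ci_high, "se": e.se}
                for c, e in self.per_class_auc.items()
            },
            "overall_auc_weighted": self.overall_auc_weighted,
            "overall_auc_unweighted": self.overall_auc_unweighted,
            "operating_points": {
                c: {"threshold": t, "sensitivity": sn, "specificity": sp}
                for c, (t, sn, sp) in self.operating_points.items()
            },
            "flagged_folds": list(self.flagged_folds),
        }


def forward_select(
    X: np.ndarray, y: np.ndarray, pool_cols: np.ndarray, k: int, ridge: float,
    fold_seed: int, min_improvement: float = 1e-4,
) -> list[int]:
    """Greedy forward wrapper selection over ``pool_cols`` (0-based columns).

    Starts empty (baseline fitness 0.5) and adds the best candidate while it
    improves the cross-validated overall AUC by more than
    ``min_improvement``. May return an empty list on signal-free data.
    """
    selected: list[int] = []
    remaining = list(pool_cols)
    current = 0.5
    while remaining:
        scores = [
            subset_fitness(X, y, np.array(selected + [cand]), k, ridge, fold_seed)
            for cand in remaining
        ]
        best_i = int(np.argmax(scores))
        if scores[best_i] <= current + min_improvement:
            break
        selected.append(remaining.pop(best_i))
        current = scores[best_i]
    return selected


def loocv_evaluate(table: FeatureTable, pool: tuple[int, ...], config: PipelineConfig | None = None) -> CvReport:
    """Leave-one-out evaluation with per-fold wrapper selection.

    ``pool`` holds 1-based feature indices (the EA's optimal pool). Each case
    is held out once; greedy forward selection runs on the training cases,
    the classifier is refit on the selected subset, and the held-out class
    probabilities are recorded. Folds whose training set misses a class are
    flagged but still scored by the remaining one-vs-rest models.
    """
    cfg = config or PipelineConfig()
    if len(pool) == 0:
        raise ValueError("feature pool is empty")
    X = table.matrix
    y = np.asarray(table.labels)
    n = len(y)
    classes = tuple(sorted(set(table.labels)))
    pool_cols = np.array(sorted(set(int(i) - 1 for i in pool)), dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x10C]))
    fold_seed = int(rng.integers(2**31))

    probs = np.zeros((n, len(classes)))
    per_fold_selected: list[tuple[int, ...]] = []
    flagged: list[int] = []
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        if len(set(y[train].tolist())) < len(classes):
            flagged.append(i)
        sel = forward_select(
            X[train], y[train], pool_cols, cfg.cv_inner_folds, cfg.ridge,
            fold_seed, cfg.wrapper_min_improvement,
        )
        per_fold_selected.append(tuple(int(c) + 1 for c in sel))
        if sel:
            model = train_multiclass_logistic(X[train][:, sel], y[train], ridge=cfg.ridge, classes=classes)
            probs[i] = model.predict_proba(X[i, sel])
        else:
            # no feature improved fitness: uninformative uniform prediction
            # (training prevalence would anti-rank the held-out class — the
            # leave-one-out prevalence artifact — and bias null AUC below 0.5)
            probs[i] = np.full(len(classes), 1.0 / len(classes))

    freq = {
        j + 1: float(np.mean([(j + 1) in s for s in per_fold_selected]))
        for j in pool_cols
    }
    per_class: dict[str, AucEstimate] = {}
    counts: dict[str, int] = {}
    operating: dict[str, tuple[float, float, float]] = {}
    for ci, cls in enumerate(classes):
        lab = y == cls
        if lab.all() or not lab.any():
            continue
        per_class[cls] = roc_auc(probs[:, ci], lab)
        counts[cls] = int(lab.sum())
        operating[cls] = best_threshold(probs[:, ci], lab)
    weighted, unweighted = overall_auc(per_class, counts)
    return CvReport(
        classes=classes,
        per_case_probabilities=probs,
        labels=list(table.labels),
        per_fold_selected=per_fold_selected,
        selection_frequency=freq,
        per_class_auc=per_class,
        overall_auc_weighted=weighted,
        overall_auc_unweighted=unweighted,
        operating_points=operating,
        flagged_folds=tuple(flagged),
    )
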