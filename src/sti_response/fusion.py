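"""Clinical model and combined (deep + clinical) model.

Logistic-regression screening of clinical factors (univariate, then
multivariate on the survivors), genetic-algorithm selection of deep
features with the clinical features always appended inside the fitness
evaluation, and an RBF-kernel SVM classifier tuned by grid search with
stratified cross-validation — the same SVM routine serves the clinical-only
model, the combined model, and the GA fitness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .metrics import roc_auc
from .synthetic import SUBTYPES, ClinicalRecord

logger = logging.getLogger("sti_response")


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 50
    generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    fitness: str = "cv_auc_svm"
    penalty_per_feature: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ConfigError("population_size must be even and >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must be in [0, 1]")
        if self.fitness != "cv_auc_svm":
            raise ConfigError(f"unknown fitness {self.fitness!r}")


@dataclass
class FeatureTable:
    patient_ids: list[str]
    deep_features: np.ndarray  # (n, d)
    clinical_features: np.ndarray  # (n, c)
    clinical_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        n = len(self.patient_ids)
        if not (len(self.deep_features) == len(self.clinical_features)
                == len(self.labels) == n):
            raise DataError("feature table rows are misaligned")
        if np.isnan(self.deep_features).any() or np.isnan(self.clinical_features).any():
            raise DataError("missing values after encoding")


CLINICAL_COLUMNS = ["age", "menopause_post", "ld_mm", "t_stage_34", "er_pos",
                    "pr_pos", "her2_pos", "ki67_pos",
                    *(f"subtype_{s}" for s in SUBTYPES)]


def encode_clinical(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Binary indicators for receptor/menopause status, ordinal T stage,
    one-hot subtype, standardized age and long diameter."""
    rows = []
    for r in records:
        row = {
            "age": r.age,
            "menopause_post": float(r.menopause == "post"),
            "ld_mm": r.baseline_LD_mm,
            "t_stage_34": float(r.clinical_T_stage == "T3-T4"),
            "er_pos": float(r.er == "positive"),
            "pr_pos": float(r.pr == "positive"),
            "her2_pos": float(r.her2 == "positive"),
            "ki67_pos": float(r.ki67 == "positive"),
        }
        for s in SUBTYPES:
            row[f"subtype_{s}"] = float(r.molecular_subtype == s)
        rows.append(row)
    df = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    for col in ("age", "ld_mm"):
        sd = df[col].std(ddof=0)
        df[col] = (df[col] - df[col].mean()) / (sd if sd > 0 else 1.0)
    return df


def _logit_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """P-values of a logistic fit (intercept + covariates); flags perfect
    separation, in which case a ridge-penalized fit is used and the p-values
    of the affected fit are returned as zeros (factor retained, flagged)."""
    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if np.any(np.abs(res.params[1:]) > 15.0):
                raise np.linalg.LinAlgError("quasi-separation")
            return np.asarray(res.pvalues[1:]), False
        except Exception:
            # penalized fallback keeps the factor in play rather than dropping it
            res = sm.Logit(y, design).fit_regularized(alpha=1.0, disp=0)
            return np.zeros(design.shape[1] - 1), True


def screen_clinical_factors(features: pd.DataFrame, labels, alpha: float = 0.05,
                            ) -> tuple[list[str], list[str]]:
    """Univariate logistic screening at ``alpha``, then a multivariate
    logistic model on the univariate survivors; returns (selected factor
    names in input column order, separation-flagged factors)."""
    y = np.asarray(labels).astype(float)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise DataError("need at least 2 cases per class")
    flagged: list[str] = []
    uni: list[str] = []
    for col in features.columns:
        x = features[[col]].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue  # constant factor carries no information
        p, sep = _logit_pvalue(x, y)
        if sep:
            flagged.append(col)
            logger.warning("perfect separation in univariate screen of %s", col)
        if p[0] < alpha:
            uni.append(col)
    if not uni:
        return [], flagged
    if len(uni) == 1:
        return list(uni), flagged
    x = features[uni].to_numpy(dtype=float)
    # exactly collinear columns (duplicates or affine negations) are fitted
    # once; the dropped column inherits its alias's selection status
    keep_idx: list[int] = []
    alias: dict[int, int] = {}
    for j in range(x.shape[1]):
        for i in keep_idx:
            if np.ptp(x[:, j] - x[:, i]) == 0 or np.ptp(x[:, j] + x[:, i]) == 0:
                alias[j] = i
                break
        else:
            keep_idx.append(j)
    p_multi, sep = _logit_pvalue(x[:, keep_idx], y)
    if sep:
        flagged.extend(uni[j] for j in keep_idx if uni[j] not in flagged)
        logger.warning("separation in multivariate screen; factors retained")
    passed: dict[int, bool] = {}
    for j, p in zip(keep_idx, p_multi):
        if np.isnan(p):  # residual collinearity: retain with a warning
            if uni[j] not in flagged:
                flagged.append(uni[j])
            logger.warning("collinearity leaves %s without a multivariate p; retained",
                           uni[j])
            passed[j] = True
        else:
            passed[j] = p < alpha
    selected = [uni[j] for j in range(len(uni)) if passed.get(alias.get(j, j), False)]
    return selected, flagged


def _svm_cv_auc(features: np.ndarray, y: np.ndarray, folds: int, seed: int,
                c: float = 1.0, gamma: str | float = "scale") -> float:
    """Mean stratified-CV AUC of an RBF SVM (decision-function scores)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c, gamma=gamma))
    scores = cross_val_predict(clf, features, y, cv=skf, method="decision_function")
    return roc_auc(scores, y)


def ga_select_features(table: FeatureTable, ga: GaConfig, folds: int = 5,
                       ) -> tuple[list[int], dict]:
    """Genetic-algorithm subset selection over the deep features.

    Binary chromosomes; fitness = mean k-fold AUC of an SVM on the selected
    deep features with the clinical features always appended, minus
    ``penalty_per_feature`` x |subset|.  Tournament selection (size 3),
    uniform crossover, bit-flip mutation, elitism of 2.  Returns the
    best-ever chromosome's indices and a per-generation fitness trace.
    """
    ga.validate()
    deep, clin = table.deep_features, table.clinical_features
    y = np.asarray(table.labels).astype(int)
    d = deep.shape[1]
    if d == 0:
        raise DataError("deep feature matrix is empty")
    rng = np.random.default_rng(ga.seed)
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key in cache:
            return cache[key]
        sel = np.nonzero(chrom)[0]
        feats = np.hstack([deep[:, sel], clin]) if sel.size else clin
        if feats.shape[1] == 0:
            val = -np.inf
        else:
            val = _svm_cv_auc(feats, y, folds, ga.seed) \
                - ga.penalty_per_feature * sel.size
        cache[key] = val
        return val

    pop = (rng.random((ga.population_size, d)) < 0.5).astype(np.int8)
    pop[0] = 0  # baseline chromosome: clinical features alone
    fits = np.array([fitness(c) for c in pop])
    best_chrom, best_fit = pop[np.argmax(fits)].copy(), float(fits.max())
    trace = [best_fit]
    for _ in range(ga.generations):
        order = np.argsort(-fits)
        elite = pop[order[:2]].copy()
        children = [*elite]
        while len(children) < ga.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population_size, size=3)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_rate:
                swap = rng.random(d) < 0.5
                a[swap], b[swap] = parents[1][swap], parents[0][swap]
            for child in (a, b):
                flip = rng.random(d) < ga.mutation_rate
                child[flip] ^= 1
                children.append(child)
        pop = np.array(children[: ga.population_size], dtype=np.int8)
        fits = np.array([fitness(c) for c in pop])
        gen_best = float(fits.max())
        if gen_best > best_fit:
            best_fit = gen_best
            best_chrom = pop[np.argmax(fits)].copy()
        trace.append(best_fit)
    if not best_chrom.any():
        logger.warning("GA best chromosome is empty; falling back to best-ever")
    return sorted(np.nonzero(best_chrom)[0].tolist()), {
        "best_fitness": best_fit, "trace": trace,
    }


DEFAULT_SVM_GRID = {"svc__C": [0.1, 1.0, 10.0], "svc__gamma": ["scale", 0.01, 0.1]}


def fit_svm(features: np.ndarray, labels, grid: dict | None = None, folds: int = 5,
            seed: int = 0):
    """RBF SVM with probability outputs; (C, gamma) by stratified grid
    search maximizing AUC.  Returns (fitted pipeline, cv report)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise DataError("both classes are required")
    grid = grid or DEFAULT_SVM_GRID
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipe = make_pipeline(StandardScaler(),
                         SVC(kernel="rbf", probability=True, random_state=seed))
    gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=skf, refit=True)
    gs.fit(np.asarray(features, dtype=float), y)
    return gs.best_estimator_, {
        "best_params": gs.best_params_,
        "cv_auc": float(gs.best_score_),
    }
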