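"""Additive marker-trait association and odds-ratio genetic risk scoring.

Binary traits use logistic regression (two-sided Wald p-values), continuous
traits linear regression. Risk scores sum odds-ratio weights times
effect-allele counts, exactly as reported — raw ORs by default, with a
``weight_kind`` switch for conventional log-OR/beta weighting. Prediction
accuracy comes from a bootstrap with 100 train(75%)/test(25%) splits, and
the classification cutoff is the candidate maximizing accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_MAF_MIN = 0.01
DEFAULT_DELTA_AIC = -5.0
DEFAULT_N_INDEPENDENT = 953_591
DEFAULT_SUGGESTIVE_ERV_LOG10 = 1.3
DEFAULT_SUGGESTIVE_SNP_LOG10 = 6.0
DEFAULT_BOOTSTRAP_REPS = 100
DEFAULT_TRAIN_FRACTION = 0.75

MISSING = -1


@dataclass
class AssociationResult:
    marker_id: str
    effect_allele: str  # "ref" | "alt"
    estimate: float  # log-odds (logistic) or slope (linear)
    odds_ratio: float | None
    p_value: float
    direction: str  # "up" | "down"
    n: int
    maf: float
    separated: bool = False


@dataclass
class GrsModel:
    markers: list[tuple[str, float, str]]  # (marker_id, weight, effect_allele)
    weight_kind: str = "odds_ratio"  # or "beta"
    cutoff: float | None = None


def _maf(genos: np.ndarray) -> float:
    aaf = genos.mean() / 2.0
    return min(aaf, 1.0 - aaf)


def additive_association(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    maf_min: float = DEFAULT_MAF_MIN,
    model: str = "logistic",
) -> list[AssociationResult]:
    """Per-marker additive regression of the phenotype on genotype counts.

    Genotype code -1 is treated as missing per marker. Markers below the
    minor-allele-frequency floor are skipped. Perfect separation yields a
    flagged result (``separated=True``) rather than a crash.
    """
    if model not in ("logistic", "linear"):
        raise ValueError(f"unknown model {model!r}")
    results: list[AssociationResult] = []
    pheno = phenotype.loc[genotypes.index]
    for marker in genotypes.columns:
        g = genotypes[marker].astype(float)
        mask = (g >= 0) & pheno.notna()
        if covariates is not None:
            mask &= covariates.notna().all(axis=1)
        g_use = g[mask].to_numpy()
        y = pheno[mask].to_numpy(dtype=float)
        if len(g_use) < 3:
            continue
        maf = _maf(g_use)
        if maf < maf_min:
            continue
        X = pd.DataFrame({"const": 1.0, "genotype": g_use})
        if covariates is not None:
            for c in covariates.columns:
                X[c] = covariates.loc[mask, c].to_numpy(dtype=float)
        est, p, separated = _fit_marker(y, X.to_numpy(), model)
        results.append(
            AssociationResult(
                marker_id=marker,
                effect_allele="alt",
                estimate=est,
                odds_ratio=float(np.exp(est)) if model == "logistic" else None,
                p_value=p,
                direction="up" if est > 0 else "down",
                n=int(mask.sum()),
                maf=float(maf),
                separated=separated,
            )
        )
    return results


def _fit_marker(y: np.ndarray, X: np.ndarray, model: str):
    if model == "linear":
        fit = sm.OLS(y, X).fit()
        return float(fit.params[1]), float(fit.pvalues[1]), False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
        est = float(fit.params[1])
        if not np.isfinite(est) or abs(est) > 15:  # diverged: separation
            return est, float("nan"), True
        return est, float(fit.pvalues[1]), False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return float("inf"), float("nan"), True


def select_covariates(
    phenotype: pd.Series,
    candidates: pd.DataFrame,
    model: str = "logistic",
    delta_aic: float = DEFAULT_DELTA_AIC,
) -> list[str]:
    """Retain each candidate covariate whose addition improves AIC by more
    than |delta_aic| relative to the intercept-only base model."""
    y = phenotype.to_numpy(dtype=float)
    base_X = np.ones((len(y), 1))
    base_aic = _fit_aic(y, base_X, model)
    retained = []
    for name in candidates.columns:
        x = candidates[name].to_numpy(dtype=float)
        X = np.column_stack([base_X, x])
        try:
            aic = _fit_aic(y, X, model)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            warnings.warn(f"covariate {name}: fit failed, skipped", stacklevel=2)
            continue
        if aic - base_aic < delta_aic:
            retained.append(name)
    return retained


def _fit_aic(y: np.ndarray, X: np.ndarray, model: str) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if model == "logistic":
            return float(sm.Logit(y, X).fit(disp=0, maxiter=50).aic)
        return float(sm.OLS(y, X).fit().aic)


def significance_thresholds(
    n_independent: int = DEFAULT_N_INDEPENDENT,
    suggestive_erv_log10: float = DEFAULT_SUGGESTIVE_ERV_LOG10,
    suggestive_snp_log10: float = DEFAULT_SUGGESTIVE_SNP_LOG10,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Bonferroni-corrected alpha plus suggestive -log10(p) cutoffs."""
    return {
        "bonferroni_alpha": alpha / n_independent,
        "suggestive_erv_minus_log10": suggestive_erv_log10,
        "suggestive_snp_minus_log10": suggestive_snp_log10,
    }


def is_suggestive(p_value: float, minus_log10_cutoff: float) -> bool:
    return -np.log10(p_value) >= minus_log10_cutoff


def genetic_risk_score(
    genotypes: Mapping[str, int] | pd.Series,
    model: GrsModel,
    missing_policy: str = "zero",
) -> tuple[float, int]:
    """OR-weighted score: sum of weight x effect-allele count per marker.

    Reference-allele effects count reference alleles (2 - genotype). Missing
    genotypes (-1 or absent marker) contribute 0 under the default policy;
    returns (score, n_missing).
    """
    score = 0.0
    n_missing = 0
    for marker_id, weight, effect_allele in model.markers:
        g = genotypes.get(marker_id, MISSING)
        g = int(g) if g is not None else MISSING
        if g == MISSING:
            n_missing += 1
            if missing_policy == "zero":
                continue
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        count = (2 - g) if effect_allele == "ref" else g
        score += weight * count
    return score, n_missing


def score_population(
    genotypes: pd.DataFrame, model: GrsModel
) -> pd.DataFrame:
    rows = {}
    for iid in genotypes.index:
        score, miss = genetic_risk_score(genotypes.loc[iid], model)
        rows[iid] = {"score": score, "n_missing_markers": miss}
    return pd.DataFrame.from_dict(rows, orient="index")


def bootstrap_accuracy(
    scores: Sequence[float],
    labels: Sequence[int],
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    max_resplits: int = 25,
) -> tuple[float, np.ndarray]:
    """Mean test accuracy of a single-predictor logistic model on the score.

    Each rep draws a random train/test split; splits whose training half
    lacks a class are redrawn (bounded retries). Regularized logistic
    fitting (scikit-learn) keeps perfectly separated scores well-defined.
    """
    from sklearn.linear_model import LogisticRegression

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("need two classes for bootstrap accuracy")
    rng = np.random.default_rng(seed)
    n = len(scores)
    n_train = max(int(round(train_fraction * n)), 1)
    accs = np.empty(reps)
    for rep in range(reps):
        for _ in range(max_resplits):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if len(set(labels[train])) == 2 and len(test) > 0:
                break
        else:
            raise RuntimeError("could not draw a split with both classes")
        clf = LogisticRegression(C=1e6)
        clf.fit(scores[train, None], labels[train])
        accs[rep] = float(np.mean(clf.predict(scores[test, None]) == labels[test]))
    return float(accs.mean()), accs


def choose_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    candidates: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cutoff maximizing classification accuracy (score > cutoff -> case).

    Default candidates are midpoints between sorted unique scores; ties
    break toward the smallest cutoff. Returns (cutoff, accuracy).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if candidates is None:
        uniq = np.unique(scores)
        if len(uniq) == 1:
            candidates = [float(uniq[0])]
        else:
            candidates = [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    if len(candidates) == 0:
        raise ValueError("no candidate cutoffs")
    best_cut, best_acc = None, -1.0
    for cut in sorted(candidates):
        acc = float(np.mean((scores > cut).astype(int) == labels))
        if acc > best_acc:
            best_cut, best_acc = float(cut), acc
    return best_cut, best_acc
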