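"""Additive-model association tests with covariate adjustment.

Each test regresses the trait on a minor-allele or minor-cluster dose in
{0, 1, 2} plus covariates and an intercept.  Quantitative traits use OLS
with Wald t inference; when the trait is log-transformed to normalise its
distribution, the p-value comes from the transformed fit while the reported
effect and SE come from a companion fit on the raw scale, so effects stay in
trait units.  Binary traits use maximum-likelihood logistic regression with
Wald z inference.  Multiplicity is controlled by Bonferroni across all
single-SNP and diplotype tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .diplotype_coding import DiplotypePattern, assign_minor_major, code_samples, minor_dose
from .errors import CollinearityError, ConfigurationError, DataError, SeparationError
from .genotype_io import MISSING, GenotypeMatrix

MIN_COMPLETE_CASES = 10


@dataclass
class AssociationResult:
    test_id: str
    minor_label: str
    major_label: str
    counts: tuple[int, int, int]  # (minor-homo, het, major-homo) among used samples
    effect: float
    stderr: float
    p_value: float
    n_used: int
    converged: bool = True
    significant: bool | None = None
    threshold: float | None = None
    extra: dict = field(default_factory=dict)


def _design(
    dose: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Listwise-complete design matrix [const, dose, covariates] + names."""
    dose = np.asarray(dose, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if covariates is None:
        cov = np.empty((len(dose), 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
        names = list(covariates.columns)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = [f"covar{k}" for k in range(cov.shape[1])]
    mask = np.isfinite(dose) & np.isfinite(trait) & np.isfinite(cov).all(axis=1)
    X = np.column_stack([np.ones(mask.sum()), dose[mask], cov[mask]])
    return X, trait[mask], ["const", "dose", *names]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.ptp(X[:, 1]) == 0:
        raise CollinearityError("dose")
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the first column whose removal does not reduce the rank
    for k in range(1, X.shape[1]):
        if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank:
            raise CollinearityError(names[k])
    raise CollinearityError("unknown")


def _dose_counts(dose: np.ndarray) -> tuple[int, int, int]:
    return (
        int((dose == 2).sum()),
        int((dose == 1).sum()),
        int((dose == 0).sum()),
    )


def linear_assoc(
    dose: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    log_transform: bool = False,
    dual: bool = True,
    test_id: str = "",
    minor_label: str = "minor",
    major_label: str = "major",
) -> AssociationResult:
    """OLS of trait on dose + covariates; two-sided Wald t-test on dose.

    With ``log_transform`` and ``dual`` (the default), the p-value is taken
    from the log-scale fit and the effect/SE from a second fit on the raw
    trait, so both a normalised test and an interpretable effect are
    reported; ``dual=False`` reports everything from the single transformed
    fit.
    """
    X, y, names = _design(dose, trait, covariates)
    if len(y) < MIN_COMPLETE_CASES:
        raise DataError(f"only {len(y)} complete cases (minimum {MIN_COMPLETE_CASES})")
    _check_rank(X, names)
    if log_transform:
        if (y <= 0).any():
            raise DataError("log transform requires a strictly positive trait")
        fit_log = sm.OLS(np.log(y), X).fit()
        p = float(fit_log.pvalues[1])
        if dual:
            fit_raw = sm.OLS(y, X).fit()
            effect, se = float(fit_raw.params[1]), float(fit_raw.bse[1])
        else:
            effect, se = float(fit_log.params[1]), float(fit_log.bse[1])
    else:
        fit = sm.OLS(y, X).fit()
        effect, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    return AssociationResult(
        test_id=test_id,
        minor_label=minor_label,
        major_label=major_label,
        counts=_dose_counts(X[:, 1]),
        effect=effect,
        stderr=se,
        p_value=p,
        n_used=len(y),
    )


def logistic_assoc(
    dose: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    test_id: str = "",
    minor_label: str = "minor",
    major_label: str = "major",
) -> AssociationResult:
    """ML logistic fit; effect is the log-odds per minor dose (Wald z test)."""
    X, y, names = _design(dose, trait, covariates)
    if len(y) < MIN_COMPLETE_CASES:
        raise DataError(f"only {len(y)} complete cases (minimum {MIN_COMPLETE_CASES})")
    if not (set(np.unique(y)) <= {0.0, 1.0}) or len(np.unique(y)) < 2:
        raise DataError("binary trait must contain both classes among complete cases")
    _check_rank(X, names)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed for {test_id!r}: {exc}") from exc
    # statsmodels >= 0.13 may warn instead of raising; enormous SEs flag it
    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged or not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise SeparationError(f"complete or quasi-complete separation in {test_id!r}")
    return AssociationResult(
        test_id=test_id,
        minor_label=minor_label,
        major_label=major_label,
        counts=_dose_counts(X[:, 1]),
        effect=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_used=len(y),
        converged=converged,
    )


def single_snp_assoc(
    g: GenotypeMatrix,
    snp_index: int,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model: str = "linear",
    log_transform: bool = False,
    dual: bool = True,
) -> AssociationResult:
    """Additive single-SNP test: dose = minor-allele count.

    The counts triplet is (minor-homozygote, heterozygote, major-homozygote)
    among the samples actually used.
    """
    snp = g.snps[snp_index]
    if snp.allele_b is None:
        raise DataError(f"SNP {snp.id} is monomorphic")
    n_a, n_b = g.allele_counts(snp_index)
    minor_is_b = n_b <= n_a
    d = g.dosage()[:, snp_index].astype(float)
    d[d == MISSING] = np.nan
    dose = d if minor_is_b else 2.0 - d
    minor = snp.allele_b if minor_is_b else snp.allele_a
    major = snp.allele_a if minor_is_b else snp.allele_b
    kwargs = dict(
        test_id=snp.id, minor_label=minor, major_label=major
    )
    if model == "linear":
        return linear_assoc(
            dose, trait, covariates, log_transform=log_transform, dual=dual, **kwargs
        )
    if model == "logistic":
        return logistic_assoc(dose, trait, covariates, **kwargs)
    raise ConfigurationError(f"unknown model {model!r}")


def diplotype_assoc(
    pattern: DiplotypePattern,
    diplos,
    H,
    rare,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model: str = "linear",
    log_transform: bool = False,
    dual: bool = True,
) -> AssociationResult:
    """Code one pattern, orient minor/major, and run the additive test.

    ``trait``/``covariates`` must be aligned to the phased samples in
    ``diplos`` (same order).
    """
    coded = code_samples(pattern, diplos, H, rare)
    mm = assign_minor_major(pattern, coded)
    dose = minor_dose(coded, mm.flipped)
    kwargs = dict(
        test_id=pattern.test_id, minor_label=mm.minor_label, major_label=mm.major_label
    )
    if model == "linear":
        res = linear_assoc(
            dose, trait, covariates, log_transform=log_transform, dual=dual, **kwargs
        )
    elif model == "logistic":
        res = logistic_assoc(dose, trait, covariates, **kwargs)
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    return res


def bonferroni(
    results: Sequence[AssociationResult], alpha: float = 0.05
) -> tuple[list[AssociationResult], float]:
    """Flag each result significant iff p < alpha / (number of tests)."""
    if not results:
        raise ConfigurationError("bonferroni: no results to correct")
    threshold = alpha / len(results)
    out = [
        replace(r, significant=r.p_value < threshold, threshold=threshold)
        for r in results
    ]
    return out, threshold


def write_results_tsv(results: Sequence[AssociationResult], path) -> None:
    """Result table mirroring the single-SNP / diplotype report layout."""
    with open(path, "w") as fh:
        fh.write(
            "test_id\tminor_major\tcounts\teffect\tstderr\tp_value\tn_used\tsignificant\n"
        )
        for r in results:
            counts = "/".join(str(c) for c in r.counts)
            sig = "" if r.significant is None else str(int(r.significant))
            fh.write(
                f"{r.test_id}\t{r.minor_label}; {r.major_label}\t{counts}\t"
                f"{r.effect:.4g}\t{r.stderr:.4g}\t{r.p_value:.2E}\t{r.n_used}\t{sig}\n"
            )
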