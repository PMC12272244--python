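"""Sensitivity/specificity comparison of dMRI-estimated and
morphometry-derived metrics across samples.

For every (dMRI metric, EM metric) pair the module computes the Pearson
correlation with a t-test p-value (N - 2 degrees of freedom), a Fisher-z
95% confidence interval (variance 1/(N - 3)), Benjamini-Hochberg FDR
q-values across the matrix, and Lin's concordance correlation coefficient
where agreement with the identity line is expected.  Sensitivity is read
off the diagonal of the corresponding-pair submatrix (each metric should
correlate with its own histological counterpart); specificity is the
absence of significant off-diagonal correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

# corresponding (dMRI, EM) metric pairs of the validation design
DEFAULT_PAIRING = {"f": "f", "theta_p2": "theta", "Da": "Da_pred"}

__all__ = [
    "CorrResult",
    "pearson_with_ci",
    "fdr_bh",
    "ccc",
    "correlation_matrix",
    "specificity_report",
    "permutation_pvalue",
    "DEFAULT_PAIRING",
    "ALPHA",
]


@dataclass
class CorrResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    q: float | None = None
    rho_c: float | None = None

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


def pearson_with_ci(x, y, alpha: float = ALPHA) -> CorrResult:
    """Pearson rho with t-test p (N-2 dof) and Fisher-z CI (var 1/(N-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need N >= 4 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    rho, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    halfwidth = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return CorrResult(rho=float(rho), p=float(p),
                      ci_low=float(np.tanh(z - halfwidth)),
                      ci_high=float(np.tanh(z + halfwidth)), n=n)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population 1/N moments):
    2 cov / (var x + var y + (mean x - mean y)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need N >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()            # 1/N convention
    cov = np.mean((x - mx) * (y - my))
    den = vx + vy + (mx - my) ** 2
    if den == 0:
        raise ValueError("degenerate inputs: ccc undefined")
    return float(2.0 * cov / den)


def permutation_pvalue(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(stats.pearsonr(x, y)[0])
    count = 0
    for _ in range(n_perm):
        r = abs(stats.pearsonr(x, rng.permutation(y))[0])
        if r >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def correlation_matrix(dmri: pd.DataFrame, em: pd.DataFrame
                       ) -> pd.DataFrame:
    """All (dMRI column) x (EM column) Pearson correlations with p, CI and
    matrix-wide BH q-values.  Rows of the two tables must be paired."""
    if len(dmri) != len(em):
        raise ValueError("tables must have matching paired rows")
    records = []
    for dc in dmri.columns:
        for ec in em.columns:
            x = dmri[dc].to_numpy()
            y = em[ec].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                # constant metric (e.g. an estimator-fixed parameter):
                # correlation undefined, excluded from FDR
                records.append({"dmri_metric": dc, "em_metric": ec,
                                "rho": np.nan, "p": np.nan,
                                "ci_low": np.nan, "ci_high": np.nan,
                                "n": len(x)})
                continue
            r = pearson_with_ci(x, y)
            records.append({"dmri_metric": dc, "em_metric": ec,
                            "rho": r.rho, "p": r.p,
                            "ci_low": r.ci_low, "ci_high": r.ci_high,
                            "n": r.n})
    table = pd.DataFrame.from_records(records)
    defined = table["p"].notna()
    q = np.full(len(table), np.nan)
    if defined.any():
        q[defined.to_numpy()] = fdr_bh(table.loc[defined, "p"].to_numpy())
    table["q"] = q
    return table


def specificity_report(dmri: pd.DataFrame, em: pd.DataFrame,
                       pairing: dict[str, str] = None,
                       alpha: float = ALPHA) -> dict:
    """Sensitivity/specificity summary of the correlation matrix.

    ``pairing`` maps each dMRI metric to its corresponding EM metric;
    diagonal entries are expected significant (sensitivity), off-diagonal
    entries of the submatrix are expected non-significant (specificity).
    """
    pairing = dict(DEFAULT_PAIRING if pairing is None else pairing)
    missing = [c for c in pairing if c not in dmri.columns]
    missing += [c for c in pairing.values() if c not in em.columns]
    if missing:
        raise ValueError(f"pairing refers to absent columns: {missing}")
    table = correlation_matrix(dmri[list(pairing)],
                               em[list(pairing.values())])
    diag, offdiag = [], []
    for _, row in table.iterrows():
        if pairing[row["dmri_metric"]] == row["em_metric"]:
            diag.append(row)
        else:
            offdiag.append(row)
    sensitivity = {r["dmri_metric"]: bool(r["q"] < alpha) for r in diag}
    spurious = [(r["dmri_metric"], r["em_metric"]) for r in offdiag
                if r["q"] < alpha]
    # concordance for the angle pair when present
    rho_c = None
    for dc, ec in pairing.items():
        if "theta" in dc:
            rho_c = ccc(dmri[dc].to_numpy(), em[ec].to_numpy())
    return {
        "matrix": table,
        "sensitivity": sensitivity,
        "n_sensitive": sum(sensitivity.values()),
        "spurious_correlations": spurious,
        "specific": len(spurious) == 0,
        "theta_ccc": rho_c,
    }
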