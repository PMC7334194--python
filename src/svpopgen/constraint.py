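"""Gene-level depletion of rare functional SVs against a covariate expectation.

Observed rare-SV counts per gene are modelled with a Poisson log-linear
regression on gene covariates (log10 transcript length, exon count, log10
total intron length, optional context flags). Because an intercept-bearing
Poisson ML fit reproduces the total observed count, the aggregate
observed/expected (O/E) ratio is exactly 1 under the fitted model; per-gene
O/E below 1 indicates depletion. Depletion is reported as 1 − O/E so larger
means more constrained, and its relationship to an external SNV-constraint
ranking is summarized in ~equal-occupancy rank bins with a two-sided
Spearman test and a 21-point rolling mean.

Per-gene point estimates at desk-scale counts are noisy; genes with expected
counts below 0.1 are flagged uninformative rather than scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import rolling_mean
from .annotation import GeneModel

MIN_EXPECTED = 0.1


def gene_covariates(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "log10_tx_length": np.log10(max(g.transcript_length, 1)),
            "n_exons": g.n_exons,
            "log10_intron_length": np.log10(max(g.total_intron_length, 1)),
            "constraint_rank": g.constraint_rank,
        })
    return pd.DataFrame(rows)


@dataclass
class GeneExpectationModel:
    params: pd.Series
    schema: list[str]
    fitted: pd.DataFrame = field(repr=False, default=None)  # gene_id, observed, expected

    def expected_for(self, covariates: pd.DataFrame) -> np.ndarray:
        x = covariates[self.schema[1:]].copy()
        x.insert(0, "const", 1.0)
        return np.exp(x.to_numpy() @ self.params.to_numpy())


def fit_expected_counts(covariates: pd.DataFrame, observed: pd.Series | np.ndarray,
                        feature_cols: tuple[str, ...] = (
                            "log10_tx_length", "n_exons", "log10_intron_length"),
                        min_genes: int = 500) -> GeneExpectationModel:
    """Poisson regression of observed per-gene counts on gene covariates."""
    if len(covariates) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(covariates)}")
    y = np.asarray(observed, dtype=float)
    if len(y) != len(covariates):
        raise ValueError("observed counts do not match the gene table")
    x = covariates[list(feature_cols)].astype(float).copy()
    if (x.nunique() <= 1).all():
        # all-identical covariates: intercept-only fit
        x = x.iloc[:, :0]
    x.insert(0, "const", 1.0)
    try:
        res = sm.GLM(y, x, family=sm.families.Poisson()).fit()
    except Exception as err:
        raise RuntimeError(f"expectation model failed to converge: {err}") from err
    if not res.converged:
        raise RuntimeError("expectation model did not converge")
    fitted = pd.DataFrame({
        "gene_id": covariates["gene_id"].to_numpy(),
        "observed": y,
        "expected": np.asarray(res.mu),
    })
    fitted["oe"] = fitted["observed"] / fitted["expected"]
    fitted["uninformative"] = fitted["expected"] < MIN_EXPECTED
    schema = ["const"] + [c for c in feature_cols if c in x.columns]
    return GeneExpectationModel(params=res.params, schema=schema, fitted=fitted)


def binned_constraint_correlation(gene_oe: pd.DataFrame, n_bins: int = 100,
                                  rolling_window: int = 21) -> dict:
    """Depletion vs SNV-constraint rank in ~equal rank bins.

    ``gene_oe`` needs columns constraint_rank, observed, expected. Bin-level
    depletion is 1 − sum(observed)/sum(expected) (aggregated, not averaged,
    for stability at low counts); bins with zero expected count are excluded
    with a flag in the output. Rank 1 = most constrained; bins are ordered
    least→most constrained, so stronger depletion among constrained genes
    yields a positive Spearman rho of bin index against depletion.
    """
    df = gene_oe.dropna(subset=["constraint_rank"]).sort_values(
        "constraint_rank", ascending=False)
    if not len(df):
        raise ValueError("no genes with a constraint rank")
    n_bins = min(n_bins, len(df))
    chunks = [df.iloc[idx] for idx in np.array_split(np.arange(len(df)), n_bins)]
    rows = []
    for i, chunk in enumerate(chunks):
        exp = chunk["expected"].sum()
        if exp <= 0:
            rows.append({"bin": i, "n_genes": len(chunk), "depletion": np.nan,
                         "excluded": True})
            continue
        rows.append({
            "bin": i, "n_genes": len(chunk),
            "depletion": float(1.0 - chunk["observed"].sum() / exp),
            "excluded": False,
        })
    bins = pd.DataFrame(rows)
    ok = bins[~bins["excluded"]]
    rho, p = stats.spearmanr(ok["bin"], ok["depletion"])
    bins.loc[~bins["excluded"], "depletion_smoothed"] = rolling_mean(
        ok["depletion"].to_numpy(), rolling_window)
    return {"bins": bins, "spearman_rho": float(rho), "p_two_sided": float(p),
            "n_bins_used": int(len(ok))}
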