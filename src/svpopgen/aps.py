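"""Adjusted proportion of singletons (APS).

The raw singleton proportion of a variant set confounds selection with SV
class, size and genomic context (larger SVs are rarer regardless of
function). APS removes the technical component by fitting a binomial
regression (logit link) of the per-site singleton indicator on those
covariates in a neutral reference stratum — intergenic, biallelic, PASS
sites — and scoring any query set as

    APS = observed singleton proportion − mean model-predicted proportion.

Zero therefore means "singleton proportion comparable to intergenic SVs of
the same class/size/context"; positive values indicate purifying selection.
Confidence intervals come from bootstrap resampling of query sites and the
significance test is a one-tailed t-test of per-site residuals against 0.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import rolling_mean

DEFAULT_COVARIATES = ("svtype", "log10_svlen")


def build_covariates(sites: pd.DataFrame,
                     extra_flags: tuple[str, ...] = ()) -> pd.DataFrame:
    """Design matrix: SV-class indicators, log10 size and optional flags."""
    x = pd.DataFrame(index=sites.index)
    classes = sorted(sites["svtype"].unique())
    for c in classes[1:]:  # first class absorbed by the intercept
        x[f"class_{c}"] = (sites["svtype"] == c).astype(float)
    x["log10_svlen"] = np.log10(sites["svlen"].clip(lower=1))
    for flag in extra_flags:
        x[flag] = sites[flag].astype(float)
    x.insert(0, "const", 1.0)
    return x


@dataclass
class APSModel:
    """Fitted singleton model with its covariate schema."""

    params: pd.Series
    schema: list[str]
    classes: list[str]
    extra_flags: tuple[str, ...] = ()
    reference_label: str = "intergenic"
    diagnostics: dict = field(default_factory=dict)
    dropped: tuple[str, ...] = ()  # constant-in-reference covariates

    def design(self, sites: pd.DataFrame) -> pd.DataFrame:
        x = pd.DataFrame(index=sites.index)
        for c in self.classes[1:]:
            x[f"class_{c}"] = (sites["svtype"] == c).astype(float)
        x["log10_svlen"] = np.log10(sites["svlen"].clip(lower=1))
        for flag in self.extra_flags:
            if flag not in sites.columns:
                raise ValueError(f"query sites lack model covariate {flag!r}")
        for flag in self.extra_flags:
            x[flag] = sites[flag].astype(float)
        x = x.drop(columns=list(self.dropped), errors="ignore")
        x.insert(0, "const", 1.0)
        if list(x.columns) != self.schema:
            raise ValueError(
                f"covariate schema mismatch: {list(x.columns)} != {self.schema}")
        return x

    def predict(self, sites: pd.DataFrame) -> np.ndarray:
        x = self.design(sites)
        eta = x.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self, path):
        payload = {
            "params": self.params.to_dict(),
            "schema": self.schema,
            "classes": self.classes,
            "extra_flags": list(self.extra_flags),
            "reference_label": self.reference_label,
            "diagnostics": self.diagnostics,
            "dropped": list(self.dropped),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "APSModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(pd.Series(p["params"])[p["schema"]], p["schema"], p["classes"],
                   tuple(p["extra_flags"]), p["reference_label"], p["diagnostics"],
                   tuple(p.get("dropped", ())))


def fit_singleton_model(reference_sites: pd.DataFrame,
                        extra_flags: tuple[str, ...] = (),
                        min_sites: int = 200) -> APSModel:
    """Fit the covariate model on the neutral reference stratum.

    ``reference_sites`` needs columns is_singleton, svtype, svlen (plus any
    extra flag columns). The maximum-likelihood intercept guarantees the
    in-sample mean prediction equals the observed singleton fraction, so the
    reference stratum scores APS = 0 by construction.
    """
    if len(reference_sites) < min_sites:
        raise ValueError(
            f"need >= {min_sites} reference sites, got {len(reference_sites)}")
    x = build_covariates(reference_sites, extra_flags)
    dropped = tuple(c for c in x.columns
                    if c != "const" and x[c].nunique() <= 1)
    x = x.drop(columns=list(dropped))
    y = reference_sites["is_singleton"].astype(float)
    model = sm.GLM(y, x, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # separation / non-convergence
        raise RuntimeError(f"singleton model failed to converge: {err}") from err
    if not res.converged:
        raise RuntimeError("singleton model did not converge")
    return APSModel(
        params=res.params,
        schema=list(x.columns),
        classes=sorted(reference_sites["svtype"].unique()),
        extra_flags=extra_flags,
        diagnostics={"deviance": float(res.deviance), "n": int(len(y)),
                     "converged": bool(res.converged)},
        dropped=dropped,
    )


@dataclass
class APSResult:
    label: str
    n_sites: int
    observed: float
    expected: float
    aps: float
    ci: tuple[float, float]
    p_one_tailed: float
    degenerate_ci: bool = False


def aps(query_sites: pd.DataFrame, model: APSModel, n_bootstrap: int = 100,
        seed: int = 0, label: str = "query") -> APSResult:
    """Score a query set: observed − expected singleton proportion.

    The 95% CI bootstraps query sites (100-fold by default); the p-value is
    a one-tailed t-test of site-level residuals (observed − predicted) > 0.
    Single-site queries get a degenerate CI flag.
    """
    if not len(query_sites):
        raise ValueError("empty query set")
    pred = model.predict(query_sites)
    obs = query_sites["is_singleton"].astype(float).to_numpy()
    point = float(obs.mean() - pred.mean())
    rng = np.random.default_rng(seed)
    n = len(obs)
    degenerate = n < 2
    if degenerate:
        ci = (point, point)
        p = float("nan")
    else:
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boots = obs[idx].mean(axis=1) - pred[idx].mean(axis=1)
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
        resid = obs - pred
        if np.allclose(resid, resid[0]):
            p = 0.0 if resid[0] > 0 else 1.0
        else:
            p = float(stats.ttest_1samp(resid, 0.0, alternative="greater").pvalue)
    return APSResult(label, n, float(obs.mean()), float(pred.mean()),
                     point, ci, p, degenerate)


def aps_by_category(sites: pd.DataFrame, model: APSModel, category_col: str,
                    n_bootstrap: int = 100, seed: int = 0) -> pd.DataFrame:
    """APS per category with Bonferroni-adjusted significance calls."""
    rows = []
    cats = sorted(sites[category_col].dropna().unique())
    for cat in cats:
        sub = sites[sites[category_col] == cat]
        if not len(sub):
            continue
        r = aps(sub, model, n_bootstrap=n_bootstrap, seed=seed, label=str(cat))
        rows.append({
            "category": r.label, "n": r.n_sites, "observed": r.observed,
            "expected": r.expected, "aps": r.aps,
            "ci_lo": r.ci[0], "ci_hi": r.ci[1], "p": r.p_one_tailed,
        })
    df = pd.DataFrame(rows)
    if len(df):
        k = len(df)
        df["significant"] = df["p"] < 0.05 / k
        df["bonferroni_k"] = k
    return df


def aps_full_vs_partial(element_aps: pd.DataFrame) -> dict:
    """Paired two-tailed t-test of full- vs partial-coverage APS.

    ``element_aps`` has one row per element class with columns aps_full and
    aps_partial (as produced by scoring full- and partial-overlap CNVs per
    class). Classes missing either stratum are dropped.
    """
    df = element_aps.dropna(subset=["aps_full", "aps_partial"])
    if len(df) < 2:
        raise ValueError("need >= 2 element classes with both strata")
    diff = df["aps_full"] - df["aps_partial"]
    if np.allclose(diff, diff.iloc[0]) and np.allclose(diff.iloc[0], 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(df["aps_full"], df["aps_partial"])
    return {"n_classes": int(len(df)), "mean_difference": float(diff.mean()),
            "t": float(t), "p_two_tailed": float(p), "pairs": df}


def score_element_classes(cnv_sites: pd.DataFrame, element_pairs: pd.DataFrame,
                          model: APSModel, n_bootstrap: int = 100,
                          seed: int = 0) -> pd.DataFrame:
    """Per-element-class APS of fully vs partially covering CNVs."""
    merged = element_pairs.merge(cnv_sites, on="sv_id", how="inner")
    rows = []
    for cls, grp in merged.groupby("element_class"):
        row = {"element_class": cls, "aps_full": np.nan, "aps_partial": np.nan}
        for stratum in ("full", "partial"):
            sub = grp[grp["category"] == stratum].drop_duplicates("sv_id")
            if len(sub) >= 2:
                row[f"aps_{stratum}"] = aps(sub, model, n_bootstrap, seed, stratum).aps
                row[f"n_{stratum}"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def aps_conservation_correlation(noncoding_cnvs: pd.DataFrame, model: APSModel,
                                 n_bins: int = 100, rolling_window: int = 21,
                                 seed: int = 0) -> dict:
    """Percentile-binned APS against per-CNV conservation sums.

    CNVs are sorted into ``n_bins`` percentile bins of their summed
    conservation score; each bin is scored with the APS model and bin rank is
    tested against bin APS with a two-sided Spearman test. A 21-point rolling
    mean (truncated at the edges) smooths the bin series. A constant
    conservation column makes the correlation undefined — flagged, not
    computed.
    """
    df = noncoding_cnvs.copy()
    if "conservation_sum" not in df.columns:
        raise ValueError("sites need a conservation_sum column")
    if df["conservation_sum"].nunique() <= 1:
        return {"defined": False, "reason": "constant conservation track"}
    df["bin"] = pd.qcut(df["conservation_sum"].rank(method="first"),
                        q=min(n_bins, len(df)), labels=False)
    rows = []
    for b, grp in df.groupby("bin"):
        pred = model.predict(grp)
        obs = grp["is_singleton"].astype(float).to_numpy()
        rows.append({"bin": int(b), "n": len(grp),
                     "aps": float(obs.mean() - pred.mean()),
                     "mean_conservation": float(grp["conservation_sum"].mean())})
    bins = pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
    rho, p = stats.spearmanr(bins["bin"], bins["aps"])
    bins["aps_smoothed"] = rolling_mean(bins["aps"].to_numpy(), rolling_window)
    return {"defined": True, "bins": bins, "spearman_rho": float(rho),
            "p_two_sided": float(p)}
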