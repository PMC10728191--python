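"""Biodiversity effects in the field and their regression on predicted PSF.

The additive partition of the net biodiversity effect splits each mixture
plot's overyielding into a complementarity effect CE = N x mean(dRY) x
mean(M) and a selection effect SE = N x cov(dRY, M), where dRY_i = B_i,mix /
M_i - 1/N is each species' deviation from its expected relative yield, M_i
its mean monoculture biomass, and cov the population covariance (divide by
N), which makes CE + SE equal the net effect exactly.  The relative yield
total RYT = sum_i B_i,mix / M_i exceeds 1 under overyielding.

Plot-level CE and RYT are then regressed on the predicted PSF effect and
the expected pathogen dilution of each plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MonocultureReference:
    """Mean monoculture biomass per species (g m^-2) with plot counts."""

    M: pd.Series
    n_plots: pd.Series

    @classmethod
    def from_biomass(cls, plot_biomass: pd.DataFrame, design: pd.DataFrame):
        """Average each species over its monoculture plots.

        ``plot_biomass`` has columns plot_id, species, biomass_g;
        ``design`` flags monocultures via richness == 1.
        """
        mono_ids = set(design.loc[design["richness"] == 1, "plot_id"])
        mono = plot_biomass[plot_biomass["plot_id"].isin(mono_ids)]
        grp = mono.groupby("species")["biomass_g"]
        return cls(M=grp.mean(), n_plots=grp.size())


def cover_to_biomass(
    surveys: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Species-specific linear regressions converting percent cover to biomass.

    ``surveys`` needs columns species, cover_pct and (for calibration rows)
    biomass_g; rows with missing biomass are predicted.  Species with fewer
    than ``min_pairs`` calibration pairs, or zero cover variance, fall back
    to a pooled regression with a warning.  Returns (per-species coefficient
    table, input with a ``biomass_pred`` column, overall Pearson r of the
    calibration pairs).
    """
    calib = surveys.dropna(subset=["biomass_g"])
    if len(calib) < min_pairs:
        raise ValueError("need at least 3 calibration pairs overall")
    pooled = stats.linregress(calib["cover_pct"], calib["biomass_g"])
    coefs = {}
    for sp, grp in calib.groupby("species"):
        if len(grp) < min_pairs or np.isclose(grp["cover_pct"].var(), 0.0):
            warnings.warn(f"species {sp!r}: pooled cover regression fallback")
            coefs[sp] = (pooled.slope, pooled.intercept, True)
        else:
            fit = stats.linregress(grp["cover_pct"], grp["biomass_g"])
            coefs[sp] = (fit.slope, fit.intercept, False)
    coef_table = pd.DataFrame(
        coefs, index=["slope", "intercept", "pooled_fallback"]
    ).T
    out = surveys.copy()
    pred = []
    for _, row in out.iterrows():
        slope, intercept, _ = coefs.get(
            row["species"], (pooled.slope, pooled.intercept, True)
        )
        pred.append(intercept + slope * row["cover_pct"])
    out["biomass_pred"] = pred
    r = float(stats.pearsonr(calib["cover_pct"], calib["biomass_g"])[0])
    return coef_table, out, r


def biodiversity_effects(
    mixture_biomass: pd.Series, reference: MonocultureReference
) -> dict:
    """Additive-partition effects for one mixture plot.

    ``mixture_biomass`` maps the plot's planted species to observed biomass
    (species harvested at zero are kept with relative yield 0, not dropped).
    """
    B = pd.Series(mixture_biomass, dtype=float)
    N = len(B)
    if N < 2:
        raise ValueError("biodiversity effects require a mixture (N >= 2)")
    missing = [s for s in B.index if s not in reference.M.index]
    if missing:
        raise KeyError(f"no monoculture reference for species: {missing}")
    M = reference.M.loc[B.index].astype(float)
    if (M <= 0).any():
        bad = list(M.index[M <= 0])
        raise ZeroDivisionError(f"monoculture biomass must be positive: {bad}")
    ry = B / M
    d_ry = ry - 1.0 / N
    ce = N * d_ry.mean() * M.mean()
    # population covariance (divide by N): the choice that makes CE + SE
    # equal the net effect identically
    se = N * float(np.mean((d_ry - d_ry.mean()) * (M - M.mean())))
    net = float(B.sum() - M.sum() / N)
    ryt = float(ry.sum())
    return {
        "N": N,
        "delta_ry": d_ry,
        "CE": float(ce),
        "SE": float(se),
        "net": net,
        "RYT": ryt,
    }


def effects_table(
    plot_biomass: pd.DataFrame, design: pd.DataFrame, reference: MonocultureReference
) -> pd.DataFrame:
    """Per-mixture-plot biodiversity effects (one row per plot, N >= 2)."""
    by_plot = plot_biomass.groupby("plot_id")
    rows = []
    meta = design.set_index("plot_id")
    for plot_id, grp in by_plot:
        if meta.loc[plot_id, "richness"] < 2:
            continue
        eff = biodiversity_effects(
            grp.set_index("species")["biomass_g"], reference
        )
        rows.append(
            {
                "plot_id": plot_id,
                "richness": eff["N"],
                "CE": eff["CE"],
                "SE": eff["SE"],
                "net": eff["net"],
                "RYT": eff["RYT"],
            }
        )
    return pd.DataFrame(rows)


def effects_regression(
    effects: pd.DataFrame,
    scores: pd.DataFrame,
    responses: tuple[str, ...] = ("CE", "RYT"),
    predictors: tuple[str, ...] = ("predicted_psf", "dilution"),
) -> pd.DataFrame:
    """OLS of each biodiversity effect on each plot-level feedback score.

    ``scores`` carries plot_id, predicted_psf and dilution.  Reports slope,
    intercept, adjusted R^2, the overall F-test p-value and n per
    (response, predictor) pair.
    """
    merged = effects.merge(scores, on="plot_id")
    if len(merged) < 10:
        raise ValueError("need at least 10 mixture plots for regression")
    rows = []
    for resp in responses:
        for pred in predictors:
            x = merged[pred].to_numpy(dtype=float)
            if np.isclose(np.var(x), 0.0):
                raise np.linalg.LinAlgError(f"predictor {pred!r} has zero variance")
            X = sm.add_constant(x)
            res = sm.OLS(merged[resp].to_numpy(dtype=float), X).fit()
            rows.append(
                {
                    "response": resp,
                    "predictor": pred,
                    "slope": float(res.params[1]),
                    "intercept": float(res.params[0]),
                    "adj_r2": float(res.rsquared_adj),
                    "f_pvalue": float(res.f_pvalue),
                    "n": int(res.nobs),
                }
            )
    return pd.DataFrame(rows)


def overyielding_tests(effects: pd.DataFrame) -> pd.DataFrame:
    """One-sided one-sample t-tests per richness: CE > 0 and RYT > 1."""
    rows = []
    for richness, grp in effects.groupby("richness", sort=True):
        if len(grp) < 2:
            warnings.warn(f"richness {richness}: single plot, test skipped")
            continue
        rec = {"richness": int(richness), "n": len(grp)}
        for col, null in (("CE", 0.0), ("RYT", 1.0)):
            x = grp[col].to_numpy(dtype=float)
            if np.isclose(x.var(ddof=1), 0.0):
                p = np.nan if np.isclose(x.mean(), null) else (0.0 if x.mean() > null else 1.0)
                rec[f"{col}_p"] = p
                rec[f"{col}_mean"] = float(x.mean())
                continue
            t = stats.ttest_1samp(x, null, alternative="greater")
            rec[f"{col}_p"] = float(t.pvalue)
            rec[f"{col}_mean"] = float(x.mean())
        rows.append(rec)
    return pd.DataFrame(rows)
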