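"""Pairwise plant-soil feedback from reciprocal-inoculation pot assays.

Log dry biomass is modeled with plant x inoculum cell means plus a
per-species seedling-height covariate.  The pairwise feedback statistic for
species A and B is the log response ratio

    PSF = ln(alpha_A) + ln(beta_B) - ln(beta_A) - ln(alpha_B)

where alpha_A is A's mean performance in A-conditioned soil, beta_A its
mean in B's soil, and so on.  Negative PSF means each species does worse in
its own soil community: the signature of specialist pathogen accumulation,
and a stabilizing force for coexistence.  Pair-level estimates carry a
delta-method variance (with the conspecific sample sizes down-weighted
because those cells are reused across the nine feedback estimates that
share them) and are pooled with a DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

STERILE = "sterile"


@dataclass
class CellMeans:
    """Adjusted (plant, inoculum) cell means of log biomass.

    ``table`` is indexed by (plant, soil) with columns ``m`` (marginal mean
    of log biomass at the species' mean seedling height), ``se`` (its
    standard error) and ``n`` (replicate count).
    """

    table: pd.DataFrame

    def m(self, plant: str, soil: str) -> float:
        return float(self.table.loc[(plant, soil), "m"])

    def se(self, plant: str, soil: str) -> float:
        return float(self.table.loc[(plant, soil), "se"])

    def n(self, plant: str, soil: str) -> int:
        return int(self.table.loc[(plant, soil), "n"])

    def has(self, plant: str, soil: str) -> bool:
        return (plant, soil) in self.table.index


@dataclass
class PairwisePSF:
    pair: tuple[str, str]
    psf: float
    var_psf: float
    group: str = ""


@dataclass
class MetaAnalysisResult:
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int
    significant: bool
    p_value: float


def fit_cell_means(
    pots: pd.DataFrame,
    biomass: str = "total",
    include_sterile: bool = False,
) -> CellMeans:
    """Fit log biomass on plant x inoculum cells with a height covariate.

    ``pots`` needs columns ``plant``, ``inoculum``, ``height_cm`` and
    ``shoot_mass_g`` / ``root_mass_g``.  The design matrix uses cell-means
    coding (one indicator per observed cell) plus one centered-height slope
    per plant species, so each cell coefficient is the adjusted mean at that
    species' mean seedling height.  Sterile controls are excluded unless
    requested (they do not enter the feedback statistic).
    """
    df = pots.copy()
    if not include_sterile:
        df = df[df["inoculum"] != STERILE]
    if biomass == "total":
        y = np.log(df["shoot_mass_g"].to_numpy() + df["root_mass_g"].to_numpy())
    elif biomass == "shoot":
        y = np.log(df["shoot_mass_g"].to_numpy())
    else:
        raise ValueError("biomass must be 'total' or 'shoot'")
    empty = df.groupby(["plant", "inoculum"]).size()
    if (empty < 1).any():  # defensive; groupby cannot yield 0 rows
        raise ValueError("cell with zero pots")
    # centered height within plant species -> coefficients are means at the
    # species' own mean height
    df = df.assign(
        _h=df["height_cm"] - df.groupby("plant")["height_cm"].transform("mean")
    )
    cells = sorted(df.groupby(["plant", "inoculum"]).groups)
    cell_idx = {c: i for i, c in enumerate(cells)}
    plants = sorted(df["plant"].unique())
    plant_idx = {p: i for i, p in enumerate(plants)}
    n_obs = len(df)
    X = np.zeros((n_obs, len(cells) + len(plants)))
    for row, (_, rec) in enumerate(df.iterrows()):
        X[row, cell_idx[(rec["plant"], rec["inoculum"])]] = 1.0
        X[row, len(cells) + plant_idx[rec["plant"]]] = rec["_h"]
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "m": res.params[: len(cells)],
            "se": res.bse[: len(cells)],
            "n": [int((df["plant"] == p).mul(df["inoculum"] == s).sum()) for p, s in cells],
        },
        index=pd.MultiIndex.from_tuples(cells, names=["plant", "soil"]),
    )
    return CellMeans(table=table)


def _require_cells(cells: CellMeans, pair: tuple[str, str]) -> None:
    a, b = pair
    needed = [(a, a), (b, b), (a, b), (b, a)]
    missing = [c for c in needed if not cells.has(*c)]
    if missing:
        raise KeyError(f"missing (plant, soil) cell(s): {missing}")


def pairwise_psf(cells: CellMeans, pair: tuple[str, str]) -> float:
    """Log-response-ratio pairwise feedback from the four cells of a pair.

    Additive in the log cell means: m[A,A] + m[B,B] - m[A,soil B] -
    m[B,soil A].  Symmetric under swapping A and B.
    """
    _require_cells(cells, pair)
    a, b = pair
    return cells.m(a, a) + cells.m(b, b) - cells.m(a, b) - cells.m(b, a)


def psf_variance_from_raw(
    means: np.ndarray,
    variances: np.ndarray,
    ns: np.ndarray,
    conspecific_effective_n: float = 1,
) -> float:
    """Delta-method variance of the feedback statistic from raw-scale cells.

    Cells are ordered (alpha_A, beta_B, alpha_B, beta_A): the two conspecific
    cells first.  Each term is Var / (N x mean^2); the conspecific cells' N
    is replaced by ``conspecific_effective_n`` (default 1 = 9 replicates / 9
    feedback estimates sharing the cell).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ns = np.asarray(ns, dtype=float).copy()
    if np.any(means == 0):
        raise ZeroDivisionError("raw-scale cell mean of zero: variance undefined")
    ns[:2] = conspecific_effective_n
    return float(np.sum(variances / (ns * means**2)))


def psf_variance(
    cells: CellMeans, pair: tuple[str, str], conspecific_effective_n: float = 1
) -> float:
    """Feedback variance from fitted cells, conspecific N down-weighted."""
    _require_cells(cells, pair)
    a, b = pair
    order = [(a, a), (b, b), (b, a), (a, b)]  # alpha_A, beta_B, alpha_B, beta_A
    means = np.array([np.exp(cells.m(p, s)) for p, s in order])
    ns = np.array([cells.n(p, s) for p, s in order], dtype=float)
    # raw-scale cell variance via the delta method: Var_x = se_log^2 * n * x^2
    variances = np.array(
        [cells.se(p, s) ** 2 for p, s in order]
    ) * ns * means**2
    return psf_variance_from_raw(means, variances, ns, conspecific_effective_n)


def estimate_pairwise_psf(
    cells: CellMeans,
    pairs,
    family: dict[str, str] | None = None,
    conspecific_effective_n: float = 1,
) -> pd.DataFrame:
    """Feedback estimate + variance for every designed pair.

    Returns a DataFrame with columns species_a, species_b, psf, var_psf and
    (if a family map is given) the family-combination ``group`` label.
    """
    rows = []
    for a, b in sorted(pairs):
        rec = {
            "species_a": a,
            "species_b": b,
            "psf": pairwise_psf(cells, (a, b)),
            "var_psf": psf_variance(cells, (a, b), conspecific_effective_n),
        }
        if family is not None:
            rec["group"] = "|".join(sorted([family[a], family[b]]))
        rows.append(rec)
    return pd.DataFrame(rows)


def meta_analyze(
    estimates, variances=None, alpha: float = 0.05
) -> MetaAnalysisResult:
    """DerSimonian-Laird random-effects pooling of pairwise feedbacks.

    Accepts either a DataFrame with ``psf``/``var_psf`` columns or two
    aligned sequences.  The pooled effect is deemed significantly different
    from zero when the normal-theory 95% CI excludes zero.
    """
    if variances is None:
        y = np.asarray(estimates["psf"], dtype=float)
        v = np.asarray(estimates["var_psf"], dtype=float)
    else:
        y = np.asarray(estimates, dtype=float)
        v = np.asarray(variances, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("meta-analysis requires at least 2 estimates")
    w = 1.0 / v
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c)
    w_re = 1.0 / (v + tau2)
    est = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = est - z * se, est + z * se
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else float(est != 0)
    return MetaAnalysisResult(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        tau2=float(tau2),
        k=k,
        significant=bool(lo > 0 or hi < 0),
        p_value=p,
    )


def group_summary(psfs: pd.DataFrame) -> pd.DataFrame:
    """Random-effects summary per family combination plus overall.

    ``psfs`` needs columns ``psf``, ``var_psf`` and ``group``.  Groups with a
    single estimate are omitted with a warning.
    """
    rows = []
    for label, grp in [("overall", psfs)] + list(psfs.groupby("group", sort=True)):
        if len(grp) < 2:
            warnings.warn(f"group {label!r} has fewer than 2 estimates; omitted")
            continue
        r = meta_analyze(grp)
        rows.append(
            {
                "group": label,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "tau2": r.tau2,
                "k": r.k,
                "significant": r.significant,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("group")
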