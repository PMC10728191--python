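"""Dissimilarity-to-PSF predictor via exhaustive AICc model averaging.

The measured pairwise plant-soil feedback (PSF) of each species pair is
regressed on up to 11 microbial-group Bray-Curtis dissimilarities.  All
2^p main-effects OLS subsets are fitted, ranked by the small-sample
corrected Akaike information criterion (AICc), and combined by Akaike
weights: per-predictor importance is the summed weight of models containing
it (important when >= 0.7), and the final linear predictor takes its slopes
from the best model restricted to the chosen predictors with a
weight-averaged intercept.

Plot-level quantities follow: predicted PSF of a plot is the
density-weighted sum of pairwise predicted PSF over heterospecific pairs,
and the expected pathogen dilution is -PSF x (1 - 1/N) for plot richness N.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .microbiome import DissimilarityMatrix

#: The three pathogen dissimilarity groups retained in the final predictor,
#: with their published slope estimates (PSF units per unit dissimilarity)
#: and the weight-averaged intercept of the exhaustive model set.
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "soil_fungal_pathogen": -1.52,
    "soil_oomycete": -2.27,
    "root_fungal_pathogen": -1.27,
}
REFERENCE_INTERCEPT: float = 1.589

IMPORTANCE_CUTOFF: float = 0.7


@dataclass(frozen=True)
class PsfPredictor:
    """Linear predictor: PSF_ij = intercept + sum_g coef_g * d_g(i, j)."""

    coefficients: Mapping[str, float]
    intercept: float

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("predictor coefficients must be finite")

    def predict(self, dissimilarities: Mapping[str, float]) -> float:
        """Predicted PSF for one species pair from its group dissimilarities."""
        total = self.intercept
        for group, coef in self.coefficients.items():
            if group not in dissimilarities:
                raise KeyError(f"missing dissimilarity for group {group!r}")
            total += coef * float(dissimilarities[group])
        return float(total)


def reference_predictor() -> PsfPredictor:
    """The published three-pathogen-group predictor."""
    return PsfPredictor(coefficients=dict(REFERENCE_COEFFICIENTS), intercept=REFERENCE_INTERCEPT)


@dataclass
class ModelSelectionResult:
    """Outcome of the exhaustive subset search.

    ``models`` has one row per fitted subset with columns ``subset`` (tuple
    of predictor names), ``coefficients`` (dict incl. 'intercept'), ``rss``,
    ``k``, ``aicc``, ``delta`` and ``weight``; ``importance`` maps predictor
    to summed Akaike weight.
    """

    models: pd.DataFrame
    importance: pd.Series
    averaged_intercept: float

    @property
    def best_model(self) -> pd.Series:
        return self.models.loc[self.models["aicc"].idxmin()]

    @property
    def important_predictors(self) -> list[str]:
        sel = self.importance[self.importance >= IMPORTANCE_CUTOFF]
        return list(sel.sort_values(ascending=False).index)


def fit_ols(X: pd.DataFrame | np.ndarray, y: Sequence[float]):
    """Least-squares fit with adjusted R^2 and the overall regression F-test.

    Returns a dict with ``params`` (pandas Series incl. const), ``rss``,
    ``adj_r2``, ``f_pvalue`` and ``n``.  Raises on rank-deficient design.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than predictors plus intercept")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear (rank-deficient) design matrix")
    res = sm.OLS(y, design).fit()
    return {
        "params": res.params,
        "rss": float(res.ssr),
        "adj_r2": float(res.rsquared_adj),
        "f_pvalue": float(res.f_pvalue),
        "n": int(res.nobs),
    }


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian OLS fit.

    ``k`` counts all estimated parameters including the intercept and the
    residual variance.  The additive constant of the Gaussian likelihood is
    dropped; it is common to all models so AICc differences are unaffected.
    """
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    if rss < 0:
        raise ValueError("RSS must be nonnegative")
    # floor RSS at numerical zero so a perfect fit stays finite and ordered
    rss = max(float(rss), n * np.finfo(float).eps ** 2)
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_m = exp(-Delta_m / 2) / sum exp(-Delta / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def exhaustive_selection(
    data: pd.DataFrame,
    predictors: Sequence[str] | None = None,
    response: str = "psf",
) -> ModelSelectionResult:
    """Fit every main-effects OLS subset (including intercept-only).

    ``data`` holds one row per species pair with the response column and one
    column per candidate predictor.  Collinear subsets are skipped with a
    warning.  Limited to 15 predictors (2^p subsets are enumerated).
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != response]
    predictors = list(predictors)
    if len(predictors) > 15:
        raise ValueError("exhaustive enumeration limited to 15 predictors")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    Xfull = data[predictors].to_numpy(dtype=float)
    ones = np.ones((n, 1))
    rows = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(range(len(predictors)), r):
            X = np.hstack([ones, Xfull[:, subset]]) if subset else ones
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(
                    f"skipping collinear subset {tuple(predictors[i] for i in subset)}"
                )
                continue
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            rss = float(resid @ resid)
            k = len(subset) + 2  # slopes + intercept + residual variance
            names = tuple(predictors[i] for i in subset)
            coeffs = {"intercept": float(coef[0])}
            coeffs.update({nm: float(c) for nm, c in zip(names, coef[1:])})
            rows.append(
                {
                    "subset": names,
                    "coefficients": coeffs,
                    "rss": rss,
                    "k": k,
                    "aicc": aicc(rss, n, k),
                }
            )
    models = pd.DataFrame(rows)
    models["delta"] = models["aicc"] - models["aicc"].min()
    models["weight"] = akaike_weights(models["aicc"].to_numpy())
    importance = pd.Series(0.0, index=predictors)
    for _, row in models.iterrows():
        for nm in row["subset"]:
            importance[nm] += row["weight"]
    averaged_intercept = float(
        (models["weight"] * models["coefficients"].map(lambda c: c["intercept"])).sum()
    )
    return ModelSelectionResult(
        models=models, importance=importance, averaged_intercept=averaged_intercept
    )


def build_predictor(
    selection: ModelSelectionResult, predictors: Sequence[str]
) -> PsfPredictor:
    """Final linear predictor: best-model slopes for the chosen predictors,
    weight-averaged intercept."""
    best = selection.best_model
    coeffs = best["coefficients"]
    missing = [p for p in predictors if p not in best["subset"]]
    if missing:
        raise ValueError(
            f"predictor(s) {missing} not in the best model {best['subset']}"
        )
    return PsfPredictor(
        coefficients={p: coeffs[p] for p in predictors},
        intercept=selection.averaged_intercept,
    )


def assemble_predictor_set(
    psfs: pd.DataFrame, dissims: Mapping[str, DissimilarityMatrix]
) -> pd.DataFrame:
    """Join measured pairwise PSF with per-group dissimilarities.

    ``psfs`` needs columns ``species_a``, ``species_b`` and ``psf``.  Returns
    one row per pair with a column per dissimilarity group plus ``psf``.
    """
    rows = []
    for _, r in psfs.iterrows():
        row = {"species_a": r["species_a"], "species_b": r["species_b"], "psf": r["psf"]}
        for group, dm in dissims.items():
            row[group] = dm.value(r["species_a"], r["species_b"])
        rows.append(row)
    return pd.DataFrame(rows).set_index(["species_a", "species_b"])


def predict_pairwise_psf(
    predictor: PsfPredictor, dissims: Mapping[str, DissimilarityMatrix]
) -> pd.DataFrame:
    """Symmetric matrix of predicted PSF for every unordered species pair."""
    groups = list(predictor.coefficients)
    for g in groups:
        if g not in dissims:
            raise KeyError(f"missing dissimilarity matrix for group {g!r}")
    species = dissims[groups[0]].species
    for g in groups[1:]:
        if dissims[g].species != species:
            raise ValueError("dissimilarity matrices must cover identical species")
    out = np.full((len(species), len(species)), predictor.intercept, dtype=float)
    for g in groups:
        out += predictor.coefficients[g] * dissims[g].d.to_numpy(dtype=float)
    return pd.DataFrame(out, index=species, columns=species)


def plot_predicted_psf(
    densities: Mapping[str, float] | pd.Series,
    psf_matrix: pd.DataFrame,
    ordered_pairs: bool = False,
) -> float:
    """Density-weighted plot-level PSF: sum over pairs of p_i p_j PSF_ij.

    ``densities`` are realized proportions of total plot biomass and must sum
    to one.  By default the sum runs over unordered heterospecific pairs
    (i < j); ``ordered_pairs=True`` doubles it (both orderings counted).
    Monocultures return 0 (no heterospecific pair).
    """
    p = pd.Series(densities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"densities must sum to 1, got {p.sum():.6f}")
    missing = [s for s in p.index if s not in psf_matrix.index]
    if missing:
        raise KeyError(f"species missing from PSF matrix: {missing}")
    total = 0.0
    species = list(p.index)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            total += p[a] * p[b] * float(psf_matrix.loc[a, b])
    return 2.0 * total if ordered_pairs else float(total)


def pathogen_dilution(predicted_psf: float, richness: int) -> float:
    """Expected pathogen dilution: -PSF x (1 - 1/N).

    The chance a neighbor is heterospecific grows as (N-1)/N with plot
    richness N; negative feedback then translates into release, hence the
    sign flip.  Monocultures (N = 1) score 0.
    """
    if richness < 1:
        raise ValueError("richness must be >= 1")
    return float(-predicted_psf * (1.0 - 1.0 / richness))
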