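"""Synthetic inputs with the structure of the field/greenhouse/sequencing data.

Everything downstream of raw data collection is testable against this
module: it reproduces the experimental designs exactly at the combinatorial
level (18 species in 3 families; 81 reciprocal pairwise feedback tests from
702 pots; 240 field plots of richness 1/2/3/6 of which 168 are mixtures)
and generates observations whose ground truth is known.

The causal chain mirrors the study system: family-structured pathogen
community dissimilarities (lowest between legume-like species, family F2)
determine true pairwise plant-soil feedbacks through the three-group linear
predictor; greenhouse pot biomass is built so the log-response-ratio
statistic on noiseless cell means returns the true feedback identically;
and field mixture yields are inflated in proportion to each plot's expected
pathogen dilution, so overyielding carries the dilution signal by
construction.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microbiome import DissimilarityMatrix, FeatureCountTable
from .predictor import REFERENCE_COEFFICIENTS, reference_predictor

#: Microbial groups driving feedback in the predictor.
PATHOGEN_GROUPS: tuple[str, ...] = tuple(REFERENCE_COEFFICIENTS)
#: The remaining candidate predictor groups (no structural relation to PSF).
NUISANCE_GROUPS: tuple[str, ...] = (
    "soil_bacteria",
    "soil_amf",
    "soil_fungal_saprobe",
    "root_rhizobia",
    "root_bacteria",
    "root_amf",
    "root_fungal_saprobe",
    "root_oomycete",
)
ALL_GROUPS: tuple[str, ...] = PATHOGEN_GROUPS + NUISANCE_GROUPS

STERILE = "sterile"


def _rng(seed: int, *purpose: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose)."""
    tags = [zlib.crc32(p.encode()) for p in purpose]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tags]))


def fam_key(fa: str, fb: str) -> str:
    """Order-free family-combination label, e.g. 'F1|F2'."""
    return "|".join(sorted([fa, fb]))


@dataclass(frozen=True)
class SpeciesPool:
    species: tuple[str, ...]
    family: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species identifiers must be unique")
        sizes = pd.Series(self.family).value_counts()
        if sizes.nunique() != 1:
            raise ValueError("family sizes must be equal")

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for sp in self.species:
            f = self.family[sp]
            if f not in seen:
                seen.append(f)
        return seen

    def members(self, fam: str) -> list[str]:
        return [sp for sp in self.species if self.family[sp] == fam]


def make_species_pool(n_families: int = 3, n_per_family: int = 6) -> SpeciesPool:
    """Deterministically named pool: species F1_S1 ... F<k>_S<m>."""
    if n_families < 1 or n_per_family < 2:
        raise ValueError("need n_families >= 1 and n_per_family >= 2")
    species = []
    family = {}
    for f in range(1, n_families + 1):
        for s in range(1, n_per_family + 1):
            name = f"F{f}_S{s}"
            species.append(name)
            family[name] = f"F{f}"
    return SpeciesPool(species=tuple(species), family=family)


def default_dissimilarity_means(n_families: int = 3) -> dict[str, dict[str, float]]:
    """Family-structured dissimilarity means per microbial group.

    For the default 3-family pool the base pattern is solved from the
    published group-level feedback ranges through the linear predictor:
    legume-like pairs (F2) least dissimilar, composite-like pairs (F3) most.
    The three pathogen groups get distinct offsets around the base pattern
    (so they are statistically separable as predictors); nuisance groups are
    flat at 0.5.
    """
    if n_families == 3:
        base = {
            "F1|F1": 0.39,
            "F2|F2": 0.20,
            "F3|F3": 0.51,
            "F1|F2": 0.31,
            "F1|F3": 0.54,
            "F2|F3": 0.37,
        }
        offsets = {
            "soil_fungal_pathogen": {
                "F1|F1": 0.08, "F2|F2": -0.04, "F3|F3": -0.04,
                "F1|F2": 0.06, "F1|F3": -0.03, "F2|F3": -0.03,
            },
            "soil_oomycete": {
                "F1|F1": -0.04, "F2|F2": 0.08, "F3|F3": -0.04,
                "F1|F2": -0.03, "F1|F3": 0.06, "F2|F3": -0.03,
            },
            "root_fungal_pathogen": {
                "F1|F1": -0.04, "F2|F2": -0.04, "F3|F3": 0.08,
                "F1|F2": -0.03, "F1|F3": -0.03, "F2|F3": 0.06,
            },
        }
    else:
        fams = [f"F{i}" for i in range(1, n_families + 1)]
        base = {}
        for i, fa in enumerate(fams):
            for fb in fams[i:]:
                base[fam_key(fa, fb)] = 0.35 if fa == fb else 0.45
        offsets = {g: {k: 0.0 for k in base} for g in PATHOGEN_GROUPS}
    means: dict[str, dict[str, float]] = {}
    for g in PATHOGEN_GROUPS:
        means[g] = {k: float(np.clip(base[k] + offsets[g][k], 0.0, 1.0)) for k in base}
    for g in NUISANCE_GROUPS:
        means[g] = {k: 0.5 for k in base}
    return means


@dataclass
class SimulationConfig:
    """Tunable study conditions for every generator.

    Fields mirror the data-generating assumptions: dissimilarity block means
    per (group, family combination); Gaussian noise around the predictor for
    true feedback; pot-level log-biomass noise and a seedling-height
    covariate; multiplicative (lognormal) field biomass noise; and the
    dimensionless gain translating a plot's expected pathogen dilution into
    mixture yield.
    """

    seed: int = 0
    n_families: int = 3
    n_per_family: int = 6
    dissimilarity_means: dict[str, dict[str, float]] | None = None
    dissimilarity_sd: float = 0.08
    psf_noise_sd: float = 0.4
    covariate_effect: float = 0.05  # log-biomass per cm of seedling height
    pot_noise_sd: float = 0.30
    sterile_bonus: float = 0.25  # log-scale advantage in pathogen-free soil
    biomass_cv: float = 0.15
    dilution_gain: float = 1.0
    monoculture_base_biomass: float = 300.0  # g m^-2
    cover_noise_sd: float = 1.5
    asv_richness: int = 30
    read_depth_range: tuple[int, int] = (1500, 3000)
    asv_count_noise: bool = True
    asv_overlap: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.dissimilarity_means is None:
            self.dissimilarity_means = default_dissimilarity_means(self.n_families)
        for name in ("dissimilarity_sd", "psf_noise_sd", "pot_noise_sd",
                     "biomass_cv", "cover_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for g, combos in self.dissimilarity_means.items():
            for k, v in combos.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"dissimilarity mean {g}/{k}={v} outside [0, 1]")
        lo, hi = self.read_depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("read_depth_range must be positive and ordered")


def make_pairing_design(pool: SpeciesPool) -> list[tuple[str, str]]:
    """Deterministic reciprocal pairing design: 3 partners per family.

    Within a family of m species the circulant graph with offsets {1, 3, 5}
    (3-regular for m = 6, giving 9 unordered pairs); between families,
    species k of the lower-indexed family meets species k, k+1, k+2 (mod m)
    of the other (18 pairs per family pair for m = 6).  For the default
    18-species pool this yields the full 81-pair design.
    """
    fams = pool.families
    pairs: set[tuple[str, str]] = set()
    for fam in fams:
        members = pool.members(fam)
        m = len(members)
        if m < 4:
            raise ValueError(f"family {fam!r} has {m} species; need >= 4")
        offsets = (1, 3, 5) if m >= 6 else (1, 2, 3)
        for i in range(m):
            for off in offsets:
                j = (i + off) % m
                if j != i:
                    pairs.add(tuple(sorted((members[i], members[j]))))
    for fa, fb in itertools.combinations(fams, 2):
        A, B = pool.members(fa), pool.members(fb)
        for k, sa in enumerate(A):
            for off in range(3):
                pairs.add(tuple(sorted((sa, B[(k + off) % len(B)]))))
    return sorted(pairs)


def simulate_dissimilarities(
    pool: SpeciesPool, config: SimulationConfig, group: str
) -> DissimilarityMatrix:
    """Family-block dissimilarity matrix with Gaussian jitter, clipped to [0,1]."""
    if group not in config.dissimilarity_means:
        raise ValueError(f"unknown microbial group {group!r}")
    means = config.dissimilarity_means[group]
    rng = _rng(config.seed, "dissimilarity", group)
    n = len(pool.species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = fam_key(pool.family[pool.species[i]], pool.family[pool.species[j]])
            val = means[key] + rng.normal(0.0, config.dissimilarity_sd)
            d[i, j] = d[j, i] = float(np.clip(val, 0.0, 1.0))
    frame = pd.DataFrame(d, index=pool.species, columns=pool.species)
    return DissimilarityMatrix(group=group, d=frame)


def simulate_all_dissimilarities(
    pool: SpeciesPool, config: SimulationConfig
) -> dict[str, DissimilarityMatrix]:
    return {g: simulate_dissimilarities(pool, config, g) for g in ALL_GROUPS}


def simulate_true_psf(
    dissims: Mapping[str, DissimilarityMatrix], config: SimulationConfig
) -> pd.DataFrame:
    """Ground-truth pairwise feedback: linear predictor + Gaussian noise.

    Requires the three pathogen predictor groups; returns one row per
    unordered species pair (columns species_a, species_b, true_psf).
    """
    missing = [g for g in PATHOGEN_GROUPS if g not in dissims]
    if missing:
        raise ValueError(f"missing predictor group(s): {missing}")
    pred = reference_predictor()
    species = dissims[PATHOGEN_GROUPS[0]].species
    rng = _rng(config.seed, "true_psf")
    rows = []
    for a, b in itertools.combinations(species, 2):
        value = pred.predict({g: dissims[g].value(a, b) for g in PATHOGEN_GROUPS})
        if config.psf_noise_sd > 0:
            value += rng.normal(0.0, config.psf_noise_sd)
        rows.append({"species_a": a, "species_b": b, "true_psf": float(value)})
    return pd.DataFrame(rows)


def psf_truth_matrix(truth: pd.DataFrame, species: Sequence[str]) -> pd.DataFrame:
    """Square symmetric matrix view of a true-PSF table (zero diagonal)."""
    m = pd.DataFrame(0.0, index=list(species), columns=list(species))
    for _, r in truth.iterrows():
        m.loc[r["species_a"], r["species_b"]] = r["true_psf"]
        m.loc[r["species_b"], r["species_a"]] = r["true_psf"]
    return m


def simulate_greenhouse(
    pool: SpeciesPool,
    pairs: Sequence[tuple[str, str]],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Pot table of the reciprocal-inoculation assay.

    Per species: 9 conspecific pots, 3 pots in each of its 9 designed
    heterospecific soils, 3 sterile controls (39 pots; 702 in the default
    design).  Cell means are constructed so the log-response-ratio feedback
    statistic on noiseless cell means equals the true pairwise PSF: with
    species baseline b_i, the cell for plant i in soil j is b_i - PSF_ij/2.
    """
    truth_m = psf_truth_matrix(truth, pool.species)
    partners: dict[str, list[str]] = {sp: [] for sp in pool.species}
    for a, b in pairs:
        partners[a].append(b)
        partners[b].append(a)
    rng = _rng(config.seed, "greenhouse")
    base = {
        sp: float(rng.normal(np.log(2.5), 0.25)) for sp in pool.species
    }  # log grams of dry biomass in own soil
    rows = []
    pot = 0
    for si, sp in enumerate(pool.species):
        shoot_frac = 0.55 + 0.02 * (si % 5)
        inocula = (
            [(sp, 9)]
            + [(p, 3) for p in sorted(partners[sp])]
            + [(STERILE, 3)]
        )
        for inoc, reps in inocula:
            if inoc == STERILE:
                m_cell = base[sp] + config.sterile_bonus
            elif inoc == sp:
                m_cell = base[sp]
            else:
                m_cell = base[sp] - float(truth_m.loc[sp, inoc]) / 2.0
            for rep in range(1, reps + 1):
                pot += 1
                height = float(rng.normal(5.0, 1.0))
                log_total = (
                    m_cell
                    + config.covariate_effect * (height - 5.0)
                    + (rng.normal(0.0, config.pot_noise_sd) if config.pot_noise_sd > 0 else 0.0)
                )
                total = float(np.exp(log_total))
                rows.append(
                    {
                        "pot_id": f"pot{pot:04d}",
                        "plant": sp,
                        "inoculum": inoc,
                        "replicate": rep,
                        "height_cm": height,
                        "shoot_mass_g": shoot_frac * total,
                        "root_mass_g": (1.0 - shoot_frac) * total,
                    }
                )
    return pd.DataFrame(rows)


def make_field_design(pool: SpeciesPool, config: SimulationConfig | None = None) -> pd.DataFrame:
    """240-plot biodiversity-manipulation design.

    Six subblocks of paired 20-plot shelters with matched compositions; per
    shelter: 6 monocultures, 3 under- and 3 over-dispersed 2-species, 2 + 2
    three-species and 2 + 2 six-species mixtures.  Under-dispersed mixtures
    draw from a single family, over-dispersed from several; compositions
    rotate round-robin so species appear in near-equal counts.  The
    precipitation label is carried as metadata only.
    """
    fams = pool.families
    if len(fams) != 3 or any(len(pool.members(f)) != 6 for f in fams):
        raise ValueError("field design requires 3 families of 6 species")
    by_fam = {f: pool.members(f) for f in fams}
    wf_pairs = {f: [] for f in fams}
    bf_pairs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in make_pairing_design(pool):
        fa, fb = pool.family[a], pool.family[b]
        if fa == fb:
            wf_pairs[fa].append((a, b))
        else:
            bf_pairs.setdefault(tuple(sorted((fa, fb))), []).append((a, b))
    fam_pair_keys = sorted(bf_pairs)
    c = {k: 0 for k in ("2u", "2o", "3u", "3o", "6u", "6o")}
    rows = []
    plot = 0
    for block in range(6):
        comps: list[tuple[int, str, tuple[str, ...]]] = []
        mono = [pool.species[(6 * block + k) % len(pool.species)] for k in range(6)]
        comps += [(1, "mono", (sp,)) for sp in mono]
        for _ in range(3):
            f = fams[c["2u"] % 3]
            comps.append((2, "under", wf_pairs[f][(c["2u"] // 3) % len(wf_pairs[f])]))
            c["2u"] += 1
        for _ in range(3):
            fp = fam_pair_keys[c["2o"] % 3]
            comps.append((2, "over", bf_pairs[fp][(c["2o"] // 3) % len(bf_pairs[fp])]))
            c["2o"] += 1
        for _ in range(2):
            f = fams[c["3u"] % 3]
            mem = by_fam[f]
            j = c["3u"] // 3
            comps.append((3, "under", (mem[j % 6], mem[(j + 1) % 6], mem[(j + 2) % 6])))
            c["3u"] += 1
        for _ in range(2):
            a = c["3o"] % 6
            comps.append(
                (3, "over", (by_fam[fams[0]][a], by_fam[fams[1]][(a + 2) % 6],
                             by_fam[fams[2]][(a + 4) % 6]))
            )
            c["3o"] += 1
        for _ in range(2):
            f = fams[c["6u"] % 3]
            comps.append((6, "under", tuple(by_fam[f])))
            c["6u"] += 1
        for _ in range(2):
            a = c["6o"] % 6
            six = tuple(
                by_fam[f][(a + off) % 6] for f in fams for off in (0, 3)
            )
            comps.append((6, "over", six))
            c["6o"] += 1
        for shelter, precip in (("A", "150%"), ("B", "50%")):
            for richness, disp, sp_tuple in comps:
                plot += 1
                rows.append(
                    {
                        "plot_id": f"P{plot:03d}",
                        "subblock": block + 1,
                        "shelter": shelter,
                        "precipitation": precip,
                        "richness": richness,
                        "dispersion": disp,
                        "composition": "|".join(sp_tuple),
                    }
                )
    return pd.DataFrame(rows)


def monoculture_means(pool: SpeciesPool, config: SimulationConfig) -> pd.Series:
    """Deterministic species monoculture biomass means (g m^-2)."""
    n = len(pool.species)
    vals = config.monoculture_base_biomass * (
        0.75 + 0.5 * np.arange(n) / max(n - 1, 1)
    )
    return pd.Series(vals, index=list(pool.species))


def plot_dilution_scores(
    design: pd.DataFrame, psf_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Planted-proportion predicted PSF and dilution per plot (truth scale)."""
    rows = []
    for _, r in design.iterrows():
        members = r["composition"].split("|")
        n = len(members)
        psf = 0.0
        for a, b in itertools.combinations(members, 2):
            psf += float(psf_matrix.loc[a, b]) / n**2
        rows.append(
            {
                "plot_id": r["plot_id"],
                "richness": n,
                "predicted_psf": psf,
                "dilution": -psf * (1.0 - 1.0 / n),
            }
        )
    return pd.DataFrame(rows)


def simulate_field_biomass(
    design: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Plot x species biomass and cover table.

    Monoculture biomass is the species mean under lognormal noise; in a
    mixture each species yields (M_i / N) x (1 + dilution_gain x plot
    dilution), where the plot dilution score comes from the true pairwise
    feedbacks at equal planted proportions.  Cover is an affine,
    species-specific function of biomass plus noise, to exercise the
    cover-to-biomass calibration.
    """
    species = sorted({s for comp in design["composition"] for s in comp.split("|")})
    pool_like = list(species)
    psf_m = psf_truth_matrix(truth, pool_like)
    m_series = config.monoculture_base_biomass * (
        0.75 + 0.5 * np.arange(len(pool_like)) / max(len(pool_like) - 1, 1)
    )
    M = pd.Series(m_series, index=pool_like)
    scores = plot_dilution_scores(design, psf_m).set_index("plot_id")
    rng = _rng(config.seed, "field_biomass")
    sp_index = {sp: i for i, sp in enumerate(pool_like)}
    rows = []
    for _, r in design.iterrows():
        members = r["composition"].split("|")
        n = len(members)
        boost = 1.0
        if n > 1:
            boost = max(
                0.05, 1.0 + config.dilution_gain * float(scores.loc[r["plot_id"], "dilution"])
            )
        for sp in members:
            noise = (
                float(np.exp(rng.normal(0.0, config.biomass_cv)))
                if config.biomass_cv > 0
                else 1.0
            )
            biomass = (M[sp] if n == 1 else M[sp] / n * boost) * noise
            i = sp_index[sp]
            cover = 2.0 + (0.12 + 0.01 * (i % 5)) * biomass
            if config.cover_noise_sd > 0:
                cover += float(rng.normal(0.0, config.cover_noise_sd))
            rows.append(
                {
                    "plot_id": r["plot_id"],
                    "species": sp,
                    "biomass_g": float(biomass),
                    "cover_pct": float(max(cover, 0.1)),
                }
            )
    return pd.DataFrame(rows)


def _block_profile(n: int, decay: float) -> np.ndarray:
    w = np.exp(-decay * np.arange(n))
    return w / w.sum()


def _lifestyles(n: int) -> tuple[list[str], list[str]]:
    """Deterministic guild labels: mostly pathogen-primary, some
    pathogen-in-secondary-only, some saprobes (filtered out)."""
    primary, secondary = [], []
    for r in range(n):
        if r % 10 == 1:
            primary.append("soil_saprotroph")
            secondary.append("")
        elif r % 10 == 6:
            primary.append("litter_saprotroph")
            secondary.append("plant_pathogen")
        else:
            primary.append("plant_pathogen")
            secondary.append("")
    return primary, secondary


def simulate_asv_tables(
    pool: SpeciesPool,
    config: SimulationConfig,
    group: str,
    plots: pd.DataFrame | None = None,
) -> FeatureCountTable:
    """Feature-count table over monoculture (and optional mixture) samples.

    Compositions are hierarchical mixtures of a global block shared by all
    species, a family-private block, and a species-private block; the
    within-family shared mass equals the configured overlap (one minus the
    target dissimilarity), so within-family Bray-Curtis is exact in the
    noise-free limit and cross-family dissimilarity increases as the shared
    global mass shrinks.  Two monoculture samples per species (matching the
    pooled paired-plot sequencing design); passing a mixture-plot design
    adds one sample per mixture whose composition is the equal-weight
    average of its members, which dilutes each species' dominant private
    pathogen by 1/N.
    """
    if group not in config.dissimilarity_means:
        raise ValueError(f"unknown microbial group {group!r}")
    fams = pool.families
    if config.asv_overlap and group in config.asv_overlap:
        overlap = config.asv_overlap[group]
    else:
        overlap = {
            k: 1.0 - v for k, v in config.dissimilarity_means[group].items()
        }
    a_f, b_f, c_f = {}, {}, {}
    for f in fams:
        o_ff = overlap[fam_key(f, f)]
        cross = [overlap[fam_key(f, g)] for g in fams if g != f]
        a = min([o_ff] + cross) if cross else 0.0
        a_f[f], b_f[f], c_f[f] = a, max(o_ff - a, 0.0), 1.0 - o_ff
    n_global = config.asv_richness
    n_family = max(5, config.asv_richness // 2)
    n_priv = max(5, config.asv_richness // 3)
    feats: list[str] = [f"{group}_G{r:03d}" for r in range(n_global)]
    fam_feats = {f: [f"{group}_{f}_P{r:03d}" for r in range(n_family)] for f in fams}
    sp_feats = {
        sp: [f"{group}_{sp}_U{r:03d}" for r in range(n_priv)] for sp in pool.species
    }
    for f in fams:
        feats += fam_feats[f]
    for sp in pool.species:
        feats += sp_feats[sp]
    index = pd.Index(feats, name="feature")
    pos = {f: i for i, f in enumerate(feats)}
    g_prof = _block_profile(n_global, 0.2)
    f_prof = _block_profile(n_family, 0.2)
    u_prof = _block_profile(n_priv, 0.8)  # steep: the head feature dominates

    comps = {}
    for sp in pool.species:
        f = pool.family[sp]
        v = np.zeros(len(feats))
        v[[pos[x] for x in feats[:n_global]]] = a_f[f] * g_prof
        v[[pos[x] for x in fam_feats[f]]] += b_f[f] * f_prof
        v[[pos[x] for x in sp_feats[sp]]] += c_f[f] * u_prof
        total = v.sum()
        comps[sp] = v / total if total > 0 else v

    rng = _rng(config.seed, "asv", group)
    lo, hi = config.read_depth_range
    counts = {}
    meta_rows = []

    def draw(comp: np.ndarray) -> np.ndarray:
        depth = int(rng.integers(lo, hi + 1))
        if config.asv_count_noise:
            return rng.multinomial(depth, comp)
        scaled = np.rint(comp * depth).astype(np.int64)
        return scaled

    for sp in pool.species:
        for rep in (1, 2):
            sid = f"{sp}_m{rep}"
            counts[sid] = draw(comps[sp])
            meta_rows.append(
                {"sample": sid, "species": sp, "type": "monoculture",
                 "composition": sp, "richness": 1}
            )
    if plots is not None:
        for _, r in plots.iterrows():
            members = str(r["composition"]).split("|")
            if len(members) < 2:
                continue
            comp = np.mean([comps[sp] for sp in members], axis=0)
            sid = str(r["plot_id"])
            counts[sid] = draw(comp)
            meta_rows.append(
                {"sample": sid, "species": "", "type": "mixture",
                 "composition": r["composition"], "richness": len(members)}
            )
    primary, secondary = _lifestyles(len(feats))
    features = pd.DataFrame(
        {"primary_lifestyle": primary, "secondary_lifestyle": secondary}, index=index
    )
    return FeatureCountTable(
        counts=pd.DataFrame(counts, index=index),
        samples=pd.DataFrame(meta_rows).set_index("sample"),
        features=features,
    )
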