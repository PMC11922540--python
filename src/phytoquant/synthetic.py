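"""Synthetic paired microscopy/metabarcoding communities with known truth.

Emulates a multi-year lake monitoring design: a station × year sample grid
of class-structured phytoplankton communities observed twice — by
microscopy (Poisson counting of a small water volume, biovolume-derived
biomass) and by amplicon sequencing (multinomial read sampling with
per-species amplification bias).  The bias model has two ingredients a
field practitioner would recognise: 18S rRNA gene copy number increasing
with cell biovolume (copy ∝ volume^b) and class-level primer efficiency
multipliers (dinoflagellates, for instance, amplify disproportionately).
Heterotrophic ASVs, many-to-one species→ASV mappings and taxa detected
only by metabarcoding make the downstream filtering and anchoring steps
exercise their real-data edge cases.

All randomness derives from a single seed via per-stage seed sequences, so
each stage and the composed dataset are individually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .asv import AsvTable
from .microscopy import SPECIES_COLUMNS

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "TruthRecord",
    "default_config",
    "unbiased_config",
    "generate_truth",
    "simulate_microscopy",
    "simulate_reads",
    "generate_dataset",
]

#: PR2-style lineage prefixes (domain;supergroup;division;class)
_LINEAGE_PREFIX = {
    "Bacillariophyceae": "Eukaryota;Stramenopiles;Ochrophyta;Bacillariophyceae",
    "Coscinodiscophyceae": "Eukaryota;Stramenopiles;Ochrophyta;Coscinodiscophyceae",
    "Mediophyceae": "Eukaryota;Stramenopiles;Ochrophyta;Mediophyceae",
    "Chrysophyceae": "Eukaryota;Stramenopiles;Ochrophyta;Chrysophyceae",
    "Cryptophyceae": "Eukaryota;Cryptista;Cryptophyta;Cryptophyceae",
    "Dinophyceae": "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae",
    "Trebouxiophyceae": "Eukaryota;Archaeplastida;Chlorophyta;Trebouxiophyceae",
    "Chlorophyceae": "Eukaryota;Archaeplastida;Chlorophyta;Chlorophyceae",
}

_HETEROTROPH_LINEAGES = [
    "Eukaryota;Alveolata;Ciliophora;Ciliophora",
    "Eukaryota;Rhizaria;Cercozoa;Cercozoa",
    "Eukaryota;Stramenopiles;Bigyra;Bicoecea",
    "Eukaryota;Opisthokonta;Fungi;Rozellomycota",
    "Eukaryota;Opisthokonta;Fungi;Aphelidiomycota",
]


@dataclass(frozen=True)
class ClassSpec:
    """One phytoplankton class in the generator.

    ``log_abundance_mean``/``sd`` parameterize the lognormal species
    abundance (cells L^-1, natural-log scale); ``log_volume_mean``/``sd``
    the lognormal cell volume (µm³); ``primer_efficiency`` the class-level
    amplification multiplier (1 = unbiased).
    """

    name: str
    n_species: int
    log_abundance_mean: float
    log_abundance_sd: float
    log_volume_mean: float
    log_volume_sd: float
    primer_efficiency: float = 1.0


def _default_classes() -> tuple[ClassSpec, ...]:
    """A spring lake community: three diatom classes, chrysophytes,
    cryptophytes, dinoflagellates and two green-algal classes.

    The community is strongly dominance-structured, as spring lake blooms
    are: araphid diatoms and chrysophytes carry most cells in their bloom
    years, single species reach a large share of the community, and the
    minor classes (greens, dinoflagellates) stay one to two orders of
    magnitude below the dominants.  Cell volumes span small greens
    (~10² µm³) to large dinoflagellates (~10⁴ µm³); dinoflagellates get an
    elevated primer efficiency on top of their volume-driven copy number.
    """
    return (
        ClassSpec("Bacillariophyceae", 4, np.log(30000), 1.3, np.log(2500), 0.7, 1.0),
        ClassSpec("Coscinodiscophyceae", 3, np.log(3000), 1.0, np.log(4000), 0.7, 0.9),
        ClassSpec("Mediophyceae", 3, np.log(8000), 1.2, np.log(1500), 0.7, 1.1),
        ClassSpec("Chrysophyceae", 8, np.log(10000), 1.3, np.log(700), 0.6, 1.2),
        ClassSpec("Cryptophyceae", 5, np.log(4000), 1.0, np.log(1200), 0.6, 1.0),
        ClassSpec("Dinophyceae", 3, np.log(800), 1.0, np.log(15000), 0.8, 2.0),
        ClassSpec("Trebouxiophyceae", 4, np.log(1500), 1.1, np.log(200), 0.6, 0.8),
        ClassSpec("Chlorophyceae", 8, np.log(2500), 1.2, np.log(300), 0.6, 0.9),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design, bias structure and observation model of the generator.

    Defaults mirror a 9-station × 3-year spring survey (27 samples) with
    class-structured amplification bias: copy number ∝ volume^0.6 and
    class primer-efficiency multipliers.  ``microscopy_count_volume`` is
    the effective water volume (L) whose cells are Poisson-counted;
    ``frac_one_to_one``/``frac_merged``/``frac_meta_only`` partition the
    species into one-to-one species↔ASV mappings, pairs merged into a
    shared genus-level ASV, and taxa detectable only by metabarcoding.
    """

    classes: tuple[ClassSpec, ...] = field(default_factory=_default_classes)
    n_stations: int = 9
    n_years: int = 3
    copy_number_exponent: float = 0.6
    read_depth: int = 50_000
    microscopy_count_volume: float = 0.005
    frac_one_to_one: float = 0.7
    frac_merged: float = 0.2
    frac_meta_only: float = 0.1
    heterotroph_asv_count: int = 22
    heterotroph_read_fraction: float = 0.4
    year_effect_sd: float = 1.5
    community_year_sd: float = 1.0
    species_year_sd: float = 1.0
    residual_sd: float = 0.6
    biomass_unit_scale: float = 1e-9
    first_year_suffix: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        for spec in self.classes:
            if spec.n_species < 1:
                raise ValueError(f"n_species must be >= 1 for class {spec.name}")
            if not spec.primer_efficiency > 0:
                raise ValueError(
                    f"primer_efficiency must be > 0 for class {spec.name}"
                )
            if spec.log_abundance_sd < 0 or spec.log_volume_sd < 0:
                raise ValueError(f"log-sds must be >= 0 for class {spec.name}")
        if self.read_depth < 100:
            raise ValueError("read_depth must be >= 100")
        if not self.microscopy_count_volume > 0:
            raise ValueError("microscopy_count_volume must be > 0")
        fracs = (self.frac_one_to_one, self.frac_merged, self.frac_meta_only)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("mapping fractions must be in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("mapping fractions must sum to 1")
        if self.heterotroph_asv_count < 0:
            raise ValueError("heterotroph_asv_count must be >= 0")
        if not 0 <= self.heterotroph_read_fraction < 1:
            raise ValueError("heterotroph_read_fraction must be in [0, 1)")
        for name in ("year_effect_sd", "community_year_sd", "species_year_sd",
                     "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["classes"] = [asdict(c) for c in self.classes]
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        doc = dict(doc)
        if "classes" in doc:
            doc["classes"] = tuple(ClassSpec(**c) for c in doc["classes"])
        return cls(**doc)


def default_config(**overrides) -> GeneratorConfig:
    """The default class-structured-bias study design."""
    return GeneratorConfig(**overrides)


def unbiased_config(**overrides) -> GeneratorConfig:
    """The same design with every amplification bias switched off.

    Copy-number exponent 0, equal primer efficiencies, no heterotrophs and
    a strictly one-to-one species↔ASV mapping: read proportions are then
    unbiased estimates of true relative abundances.
    """
    base = _default_classes()
    flat = tuple(
        ClassSpec(
            c.name, c.n_species, c.log_abundance_mean, c.log_abundance_sd,
            c.log_volume_mean, c.log_volume_sd, primer_efficiency=1.0,
        )
        for c in base
    )
    defaults = dict(
        classes=flat,
        copy_number_exponent=0.0,
        frac_one_to_one=1.0,
        frac_merged=0.0,
        frac_meta_only=0.0,
        heterotroph_asv_count=0,
        heterotroph_read_fraction=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset.

    ``abundance``: sample × species true abundances (cells L^-1).
    ``cell_volume``/``copy_number``/``class_of``: per-species Series.
    ``asv_of``: species → asv_id (shared id for merged species).
    ``microscopy_visible``: per-species bool; False for taxa only
    metabarcoding can see.  ``heterotroph_asvs``: list of non-phyto ASVs.
    """

    abundance: pd.DataFrame
    cell_volume: pd.Series
    copy_number: pd.Series
    class_of: pd.Series
    asv_of: pd.Series
    microscopy_visible: pd.Series
    heterotroph_asvs: list

    def validate(self) -> "TruthRecord":
        if (self.abundance.values < 0).any():
            raise ValueError("negative true abundances")
        if (self.cell_volume <= 0).any():
            raise ValueError("non-positive cell volumes")
        if self.class_of.isna().any():
            raise ValueError("species without a class")
        if self.asv_of.isna().any():
            raise ValueError("species without an ASV assignment")
        return self


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage of the simulation
    return np.random.default_rng([config.seed, stage])


def sample_ids(config: GeneratorConfig) -> list[str]:
    """'station_yearSuffix' labels, e.g. '1_20' … '9_22'."""
    return [
        f"{st + 1}_{config.first_year_suffix + yr}"
        for yr in range(config.n_years)
        for st in range(config.n_stations)
    ]


def generate_truth(config: GeneratorConfig) -> TruthRecord:
    """Draw the latent community and its species↔ASV mapping.

    Log abundance of species s (class c) in sample (station, year) is
    mu_c + delta_s + eta_{year,c} + eps, with delta_s a species baseline
    (sd = the class abundance log-sd), eta a shared year × class effect
    (sd = ``year_effect_sd``) that correlates stations within a year, and
    eps station-level noise (sd = ``residual_sd``).
    """
    rng = _rng(config, 0)
    ids = sample_ids(config)

    species, class_of, volumes = [], {}, {}
    for spec in config.classes:
        for k in range(spec.n_species):
            name = f"{spec.name}_sp{k + 1}"
            species.append(name)
            class_of[name] = spec.name
            volumes[name] = float(
                np.exp(rng.normal(spec.log_volume_mean, spec.log_volume_sd))
            )
    class_of = pd.Series(class_of, name="class_name")
    cell_volume = pd.Series(volumes, name="cell_volume")
    copy_number = (cell_volume ** config.copy_number_exponent).rename("copy_number")

    # log-abundance components, hierarchical by year:
    #   kappa_y    community-wide bloom intensity (shared by every species;
    #              cancels exactly in every relative quantity, so it is the
    #              signal that only absolute anchoring can recover)
    #   eta_{c,y}  class-level year effect shared by the class's species
    #              (drives the year-dominant class turnover)
    #   zeta_{s,y} species-level year individuality (species of one class
    #              bloom in different years)
    #   delta_s    which species dominate their class
    #   eps        independent station-level noise
    log_a = np.zeros((len(ids), len(species)))
    year_of_sample = np.repeat(np.arange(config.n_years), config.n_stations)
    spec_by_name = {c.name: c for c in config.classes}
    kappa = rng.normal(0.0, config.community_year_sd, size=config.n_years)
    class_year = {
        c.name: rng.normal(0.0, config.year_effect_sd, size=config.n_years)
        for c in config.classes
    }
    for j, name in enumerate(species):
        spec = spec_by_name[class_of[name]]
        delta = rng.normal(0.0, spec.log_abundance_sd)
        eta = class_year[spec.name]
        zeta = rng.normal(0.0, config.species_year_sd, size=config.n_years)
        eps = rng.normal(0.0, config.residual_sd, size=len(ids))
        log_a[:, j] = (
            spec.log_abundance_mean + delta
            + (kappa + eta + zeta)[year_of_sample] + eps
        )
    abundance = pd.DataFrame(np.exp(log_a), index=pd.Index(ids, name="sample_id"),
                             columns=species)

    # species -> ASV mapping: partition per class into 1:1 / merged / meta-only
    asv_of: dict[str, str] = {}
    visible: dict[str, bool] = {}
    counter = 1
    for spec in config.classes:
        members = [s for s in species if class_of[s] == spec.name]
        order = list(rng.permutation(members))
        n = len(order)
        n_merged = int(round(config.frac_merged * n))
        n_merged -= n_merged % 2  # merged species come in pairs
        n_meta = int(round(config.frac_meta_only * n))
        n_meta = min(n_meta, n - n_merged)
        merged, rest = order[:n_merged], order[n_merged:]
        meta_only, one_to_one = rest[:n_meta], rest[n_meta:]
        for a, b in zip(merged[0::2], merged[1::2]):
            asv_id = f"ASV{counter}_{spec.name}_genus"
            counter += 1
            asv_of[a] = asv_id
            asv_of[b] = asv_id
            visible[a] = visible[b] = True
        for s in one_to_one:
            asv_of[s] = f"ASV{counter}_{s}"
            counter += 1
            visible[s] = True
        for s in meta_only:
            asv_of[s] = f"ASV{counter}_{s}"
            counter += 1
            visible[s] = False

    het = [f"ASVh{k + 1}" for k in range(config.heterotroph_asv_count)]
    return TruthRecord(
        abundance=abundance,
        cell_volume=cell_volume,
        copy_number=copy_number,
        class_of=class_of,
        asv_of=pd.Series(asv_of, name="asv_id").reindex(species),
        microscopy_visible=pd.Series(visible, name="visible").reindex(species),
        heterotroph_asvs=het,
    ).validate()


def simulate_microscopy(truth: TruthRecord, config: GeneratorConfig) -> pd.DataFrame:
    """Poisson-count the community in a fixed water volume.

    Counted cells ~ Poisson(true abundance × counted volume), rescaled back
    to cells L^-1; biomass = abundance × cell volume × unit scale (density
    1).  Species with zero counts — and taxa microscopy cannot see — are
    absent from the returned long-format table.
    """
    rng = _rng(config, 1)
    V = config.microscopy_count_volume
    vis = truth.microscopy_visible
    rows = []
    for sid in truth.abundance.index:
        lam = truth.abundance.loc[sid] * V
        counts = rng.poisson(lam.values)
        for name, cnt in zip(truth.abundance.columns, counts):
            if cnt == 0 or not vis[name]:
                continue
            abundance = cnt / V
            biomass = abundance * truth.cell_volume[name] * config.biomass_unit_scale
            rows.append((sid, name, truth.class_of[name], abundance, biomass))
    return pd.DataFrame(rows, columns=SPECIES_COLUMNS)


def simulate_reads(truth: TruthRecord, config: GeneratorConfig) -> AsvTable:
    """Multinomial read sampling with copy-number and primer bias.

    Expected weight of a phytoplankton ASV in a sample is the sum over its
    species of true abundance × copy number × class primer efficiency.
    Heterotroph ASVs draw lognormal weights scaled so they take
    ``heterotroph_read_fraction`` of the expected library.
    """
    if config.read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    rng = _rng(config, 2)
    eff = {c.name: c.primer_efficiency for c in config.classes}

    phyto_asvs = list(dict.fromkeys(truth.asv_of))  # stable order
    asv_index = {a: k for k, a in enumerate(phyto_asvs)}
    all_asvs = phyto_asvs + list(truth.heterotroph_asvs)
    n_het = len(truth.heterotroph_asvs)

    counts = np.zeros((len(truth.abundance), len(all_asvs)), dtype=int)
    for r, sid in enumerate(truth.abundance.index):
        w = np.zeros(len(all_asvs))
        for name in truth.abundance.columns:
            w[asv_index[truth.asv_of[name]]] += (
                truth.abundance.loc[sid, name]
                * truth.copy_number[name]
                * eff[truth.class_of[name]]
            )
        if n_het:
            phyto_total = w[: len(phyto_asvs)].sum()
            f = config.heterotroph_read_fraction
            het_total = phyto_total * f / (1.0 - f)
            g = np.exp(rng.normal(0.0, 1.0, size=n_het))
            w[len(phyto_asvs):] = het_total * g / g.sum()
        counts[r] = rng.multinomial(config.read_depth, w / w.sum())

    # taxonomy: phytoplankton ASVs get their class lineage with a species
    # rank; heterotrophs cycle through typical lake heterotroph lineages
    asv_class = {}
    for name in truth.asv_of.index:
        asv_class[truth.asv_of[name]] = truth.class_of[name]
    records = []
    for a in phyto_asvs:
        cls = asv_class[a]
        prefix = _LINEAGE_PREFIX.get(cls, f"Eukaryota;unknown;unknown;{cls}")
        records.append((a, f"{prefix};{a}", cls, "phytoplankton"))
    for k, a in enumerate(truth.heterotroph_asvs):
        lin = _HETEROTROPH_LINEAGES[k % len(_HETEROTROPH_LINEAGES)]
        records.append((a, f"{lin};{a}", lin.split(";")[3], "heterotroph"))
    taxonomy = pd.DataFrame(
        records, columns=["asv_id", "lineage", "class_name", "trophic"]
    ).set_index("asv_id")

    counts_df = pd.DataFrame(counts, index=truth.abundance.index, columns=all_asvs)
    return AsvTable(counts_df, taxonomy)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, AsvTable, TruthRecord]:
    """(species table, ASV table, truth) from one seed."""
    truth = generate_truth(config)
    species = simulate_microscopy(truth, config)
    reads = simulate_reads(truth, config)
    return species, reads, truth
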