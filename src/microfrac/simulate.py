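"""Synthetic reference genomes, taxonomies and metagenome profiles.

Every pipeline stage is testable against exact ground truth generated here:

* a random rank taxonomy whose species carry known "true" genome sizes
  drawn from a log-normal law, with per-genome completeness/contamination
  back-computed so the corrected assembly size reproduces the true size
  exactly;
* condensed coverage profiles with log-normal relative abundances, a
  controlled eukaryotic (non-microbial) fraction of the sequenced bases, a
  controlled archaeal share of the community, partial taxonomic resolution
  (coverage truncated to genus/family/... per a per-rank law), and optional
  multiplicative log-normal coverage noise;
* pH/AGS datasets drawn from a Gamma GLM with known link, coefficients and
  shape, for parameter-recovery tests of the association stage.

Eukaryotic DNA is modelled purely as unattributed base pairs in a sample's
sequencing total — no eukaryotic lineages are emitted — mirroring what a
bacterial/archaeal marker-based profiler can see.  The non-microbial
fraction of a noise-free simulated sample therefore equals the configured
``euk_fraction`` by construction.

A reads-per-marker estimator of average genome size (total bases divided by
genome-equivalents of marker coverage) is included as a *foil*: it inflates
by exactly ``1/(1 - euk_fraction/100)`` when non-microbial reads enter the
numerator, which is the bias the coverage-weighted estimator avoids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .lineage import RANKS, Lineage
from .profiles import ProfileEntry, SampleProfile, write_profiles
from .taxonomy import (
    GenomeRecord,
    SizeTaxonomy,
    build_taxonomy,
    write_taxonomy,
)

ENVIRONMENTS = ("cropland", "forest", "grassland", "shrubland", "tundra")

# chain truncation law: probability that an entry resolved at a rank is
# pushed up one level (applied species -> genus -> ... -> domain -> root);
# defaults leave ~0.5% of coverage species-resolved, typical of soil
DEFAULT_TRUNCATION = {
    "species": 0.995,
    "genus": 0.5,
    "family": 0.5,
    "order": 0.5,
    "class": 0.5,
    "phylum": 0.5,
    "domain": 0.02,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Parameters of the synthetic community and sequencing model.

    Defaults emulate a soil metagenome survey: ~38.8% of sequenced bases
    non-microbial, archaea ~1.2% of the microbial community, genome sizes
    log-normal around 4 Mbp (log-sd 0.4, spanning roughly 1.5-11 Mbp), and
    heavy lineage truncation so only ~0.5% of coverage is species-resolved.
    """

    n_species: int = 150
    n_samples: int = 20
    size_log_mean: float = math.log(4e6)  # log bp
    size_log_sd: float = 0.4
    abundance_log_sd: float = 1.0
    euk_fraction: float = 38.8  # percent of total_bases that is non-microbial
    archaea_fraction: float = 1.2  # percent of microbial coverage mass
    total_bases: float = 5e9  # bp sequenced per sample
    coverage_noise_sd: float = 0.1  # log-sd of multiplicative noise; 0 = exact
    truncation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUNCATION)
    )
    completeness_range: tuple[float, float] = (70.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 10.0)
    genomes_per_species: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise SimulationError("n_species must be >= 1")
        if self.n_samples < 1:
            raise SimulationError("n_samples must be >= 1")
        if not 0 <= self.euk_fraction < 100:
            raise SimulationError("euk_fraction must be in [0, 100)")
        if not 0 <= self.archaea_fraction <= 100:
            raise SimulationError("archaea_fraction must be in [0, 100]")
        for value in (self.size_log_sd, self.abundance_log_sd, self.total_bases):
            if value <= 0:
                raise SimulationError("scale parameters must be > 0")
        if self.coverage_noise_sd < 0:
            raise SimulationError("coverage_noise_sd must be >= 0")
        for rank, p in self.truncation.items():
            if rank not in RANKS:
                raise SimulationError(f"unknown rank {rank!r} in truncation law")
            if not 0 <= p <= 1:
                raise SimulationError(f"truncation probability for {rank} not in [0,1]")
        lo, hi = self.completeness_range
        if not 0 < lo <= hi <= 100:
            raise SimulationError("completeness_range must satisfy 0 < lo <= hi <= 100")
        lo, hi = self.contamination_range
        if not 0 <= lo <= hi < 100:
            raise SimulationError("contamination_range must satisfy 0 <= lo <= hi < 100")

    # -- YAML round-trip ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SimulationError(f"{path}: spec file must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SimulationError(f"{path}: unknown spec fields {sorted(unknown)}")
        for key in ("completeness_range", "contamination_range", "genomes_per_species"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("completeness_range", "contamination_range", "genomes_per_species"):
            data[key] = list(data[key])
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Exact pre-noise ground truth for one simulated sample."""

    sample_id: str
    true_ags: float  # bp, coverage-weighted over the true species profile
    true_microbial_fraction: float  # percent
    true_non_microbial: float  # percent; the configured euk_fraction
    true_coverages: dict[str, float]  # species lineage string -> fold coverage
    total_bases: float
    euk_fraction: float


# -- taxonomy simulation ---------------------------------------------------


def _random_hierarchy(
    rng: np.random.Generator, n_species: int, domain: str, tag: str
) -> list[Lineage]:
    """Random 7-rank lineages for ``n_species`` species under one domain."""
    counts = [n_species]
    # shrink the number of taxa going up: genus, family, order, class, phylum
    for _ in range(5):
        counts.append(max(1, int(math.ceil(counts[-1] / 3))))
    n_gen, n_fam, n_ord, n_cls, n_phy = counts[1], counts[2], counts[3], counts[4], counts[5]

    phylum_of_class = rng.integers(0, n_phy, size=n_cls)
    class_of_order = rng.integers(0, n_cls, size=n_ord)
    order_of_family = rng.integers(0, n_ord, size=n_fam)
    family_of_genus = rng.integers(0, n_fam, size=n_gen)
    genus_of_species = rng.integers(0, n_gen, size=n_species)

    lineages = []
    for s in range(n_species):
        g = int(genus_of_species[s])
        f = int(family_of_genus[g])
        o = int(order_of_family[f])
        c = int(class_of_order[o])
        p = int(phylum_of_class[c])
        lineages.append(
            Lineage.from_names(
                domain,
                f"Phylum{tag}{p}",
                f"Class{tag}{c}",
                f"Order{tag}{o}",
                f"Family{tag}{f}",
                f"Genus{tag}{g}",
                f"Species{tag}{s}",
            )
        )
    return lineages


def simulate_taxonomy(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[list[GenomeRecord], SizeTaxonomy]:
    """Draw a reference genome table with exactly known species sizes.

    Species true sizes are log-normal (rounded to whole bp).  Each species
    gets 1-3 genomes whose completeness is drawn from the configured range
    and whose assembly size and contamination are back-computed so that the
    completeness/contamination correction recovers the true size exactly.
    The built taxonomy therefore carries the true sizes at its species
    nodes.  Deterministic for a given spec and seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    n_arch = 0
    if spec.archaea_fraction > 0 and spec.n_species >= 2:
        n_arch = max(1, int(round(0.1 * spec.n_species)))
    n_bact = spec.n_species - n_arch

    lineages: list[Lineage] = []
    if n_bact:
        lineages += _random_hierarchy(rng, n_bact, "Bacteria", "B")
    if n_arch:
        lineages += _random_hierarchy(rng, n_arch, "Archaea", "A")

    true_sizes = np.maximum(
        1.0,
        np.round(rng.lognormal(spec.size_log_mean, spec.size_log_sd, len(lineages))),
    )

    records: list[GenomeRecord] = []
    lo_g, hi_g = spec.genomes_per_species
    for i, (lineage, true_size) in enumerate(zip(lineages, true_sizes.tolist())):
        n_genomes = int(rng.integers(lo_g, hi_g + 1))
        for j in range(n_genomes):
            completeness = float(rng.uniform(*spec.completeness_range))
            contamination = float(rng.uniform(*spec.contamination_range))
            # back-compute assembly (ceil keeps contamination >= the draw),
            # then re-solve contamination so the correction is exact
            exact = true_size * (completeness / 100.0) / (1.0 - contamination / 100.0)
            assembly = int(math.ceil(exact))
            contamination = 100.0 * (1.0 - true_size * (completeness / 100.0) / assembly)
            records.append(
                GenomeRecord(
                    accession=f"SYN{i:05d}.{j}",
                    lineage=lineage,
                    assembly_size=assembly,
                    completeness=completeness,
                    contamination=max(0.0, contamination),
                )
            )
    return records, build_taxonomy(records)


# -- sample simulation -----------------------------------------------------


def _truncate_lineage(
    rng: np.random.Generator, lineage: Lineage, truncation: dict[str, float]
) -> Lineage:
    """Apply the chain truncation law, from species upward."""
    depth = lineage.depth
    while depth >= 1:
        p = truncation.get(RANKS[depth - 1], 0.0)
        if rng.random() < p:
            depth -= 1
        else:
            break
    return lineage.truncate(depth)


def simulate_sample(
    taxonomy: SizeTaxonomy,
    spec: SimulationSpec,
    seed: int | None = None,
    sample_id: str = "sim0",
) -> tuple[SampleProfile, SyntheticTruth]:
    """Draw one condensed coverage profile with exact ground truth.

    Relative abundances are log-normal; archaeal species' abundance mass is
    rescaled to ``archaea_fraction`` percent of the community; coverages
    are scaled so the microbial base pairs are exactly
    ``(1 - euk_fraction/100) * total_bases``; lineage truncation and
    multiplicative coverage noise are applied afterwards.  The returned
    truth records the exact pre-truncation, pre-noise state.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    species = list(taxonomy.species())
    if not species:
        raise SimulationError("taxonomy has no species nodes")
    sizes = np.array([node.ags for _, node in species])
    abund = rng.lognormal(0.0, spec.abundance_log_sd, len(species))

    is_arch = np.array([lin.name_at(1) == "d__Archaea" for lin, _ in species])
    if is_arch.any() and (~is_arch).any() and 0 < spec.archaea_fraction < 100:
        target = spec.archaea_fraction / 100.0
        arch_mass = abund[is_arch].sum()
        bact_mass = abund[~is_arch].sum()
        abund = abund.copy()
        abund[is_arch] *= target / arch_mass
        abund[~is_arch] *= (1.0 - target) / bact_mass

    microbial = (1.0 - spec.euk_fraction / 100.0) * spec.total_bases
    coverages = abund * (microbial / float(np.dot(abund, sizes)))

    true_ags = float(np.dot(coverages, sizes) / coverages.sum())
    truth = SyntheticTruth(
        sample_id=sample_id,
        true_ags=true_ags,
        true_microbial_fraction=100.0 - spec.euk_fraction,
        true_non_microbial=spec.euk_fraction,
        true_coverages={
            str(lin): float(c) for (lin, _), c in zip(species, coverages)
        },
        total_bases=spec.total_bases,
        euk_fraction=spec.euk_fraction,
    )

    observed: dict[str, tuple[Lineage, float]] = {}
    for (lin, _), cov in zip(species, coverages):
        trunc = _truncate_lineage(rng, lin, spec.truncation)
        key = str(trunc)
        prev = observed.get(key)
        observed[key] = (trunc, (prev[1] if prev else 0.0) + float(cov))

    entries = []
    for key in sorted(observed):
        lin, cov = observed[key]
        if spec.coverage_noise_sd > 0:
            cov *= float(rng.lognormal(0.0, spec.coverage_noise_sd))
        entries.append(ProfileEntry(lineage=lin, coverage=cov))

    profile = SampleProfile(
        sample_id=sample_id, entries=entries, total_bases=spec.total_bases
    )
    return profile, truth


def simulate_dataset(
    taxonomy: SizeTaxonomy, spec: SimulationSpec, seed: int | None = None
) -> tuple[list[SampleProfile], list[SyntheticTruth]]:
    """``spec.n_samples`` profiles with per-sample seed offsets."""
    base = spec.seed if seed is None else seed
    profiles, truths = [], []
    for i in range(spec.n_samples):
        prof, truth = simulate_sample(
            taxonomy, spec, seed=(base + 1009 * (i + 1)) % (2**31), sample_id=f"sim{i:03d}"
        )
        profiles.append(prof)
        truths.append(truth)
    return profiles, truths


# -- pH/AGS association simulation ----------------------------------------


def simulate_ph_dataset(
    n_samples: int,
    link: str = "log",
    intercept: float = 15.5,
    slope: float = -0.15,
    shape: float = 20.0,
    ph_range: tuple[float, float] = (3.5, 9.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (ph, ags, environment) rows from a Gamma GLM with known truth.

    pH is uniform on ``ph_range``; mean AGS follows the chosen link
    (``log``: mu = exp(a + b*ph); ``inverse``: mu = 1/(a + b*ph)); AGS is
    Gamma with that mean and the given shape (variance mu²/shape, so large
    shape approaches the noise-free mean curve).  Environment labels are
    assigned round-robin for grouped-fit tests.
    """
    if n_samples < 3:
        raise SimulationError("n_samples must be >= 3")
    if shape <= 0:
        raise SimulationError("shape must be > 0")
    rng = np.random.default_rng(seed)
    ph = rng.uniform(ph_range[0], ph_range[1], n_samples)
    eta = intercept + slope * ph
    if link == "log":
        mu = np.exp(eta)
    elif link == "inverse":
        if np.any(eta <= 0):
            raise SimulationError(
                "inverse link requires intercept + slope*ph > 0 across ph_range"
            )
        mu = 1.0 / eta
    else:
        raise SimulationError(f"unknown link {link!r}")
    ags = rng.gamma(shape, mu / shape)
    return pd.DataFrame(
        {
            "sample": [f"sim{i:03d}" for i in range(n_samples)],
            "ph": ph,
            "ags": ags,
            "environment": [ENVIRONMENTS[i % len(ENVIRONMENTS)] for i in range(n_samples)],
        }
    )


# -- the reads-per-marker foil --------------------------------------------


def reads_per_marker_foil(
    profile: SampleProfile | None,
    truth: SyntheticTruth,
    euk_fraction: float | None = None,
) -> float:
    """AGS as a naive total-bases-per-genome-equivalent estimator would see it.

    With a profile, returns ``total_bases / total_coverage`` — the estimate
    of a method that divides *all* sequenced bases (microbial or not) by
    the community's genome-equivalents.  Without one, returns the closed
    form ``true_ags / (1 - euk_fraction/100)``.  The two agree exactly for
    noise-free simulations; both inflate by ``1/(1 - euk_fraction/100)``
    relative to the true AGS.
    """
    euk = truth.euk_fraction if euk_fraction is None else euk_fraction
    if not 0 <= euk < 100:
        raise SimulationError("euk_fraction must be in [0, 100)")
    if profile is not None and profile.total_coverage > 0:
        return profile.total_bases / profile.total_coverage
    return truth.true_ags / (1.0 - euk / 100.0)


# -- run directory output --------------------------------------------------


def write_simulation(
    spec: SimulationSpec, outdir: str | Path, seed: int | None = None
) -> dict:
    """Simulate a full dataset and write it under ``outdir``.

    Emits genomes.tsv, taxonomy.tsv, profiles.tsv, metadata.tsv (with a
    uniform random pH and round-robin environment per sample), truth.json
    and manifest.json.  Returns the manifest.  Deterministic for a given
    spec and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = spec.seed if seed is None else seed
    spec = replace(spec, seed=seed)

    records, taxonomy = simulate_taxonomy(spec, seed=seed)
    profiles, truths = simulate_dataset(taxonomy, spec, seed=seed + 1)

    meta_rng = np.random.default_rng(seed + 2)
    for i, prof in enumerate(profiles):
        prof.ph = float(np.round(meta_rng.uniform(4.0, 8.5), 2))
        prof.environment = ENVIRONMENTS[i % len(ENVIRONMENTS)]

    genomes_path = outdir / "genomes.tsv"
    with genomes_path.open("w", encoding="utf-8") as fh:
        fh.write("accession\tlineage\tassembly_size\tcompleteness\tcontamination\n")
        for rec in records:
            fh.write(
                f"{rec.accession}\t{rec.lineage}\t{rec.assembly_size}\t"
                f"{rec.completeness!r}\t{rec.contamination!r}\n"
            )
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    write_profiles(profiles, outdir / "profiles.tsv", outdir / "metadata.tsv")
    with (outdir / "truth.json").open("w", encoding="utf-8") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1, sort_keys=True)

    spec_data = asdict(spec)
    for key in ("completeness_range", "contamination_range", "genomes_per_species"):
        spec_data[key] = list(spec_data[key])
    manifest = {
        "seed": seed,
        "spec": spec_data,
        "n_genomes": len(records),
        "n_samples": len(profiles),
        "files": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
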