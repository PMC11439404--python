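"""Per-sample community statistics from coverage profiles.

Given a size-annotated taxonomy and a sample's condensed coverage profile,
this module computes:

* **AGS** — the community average genome size, the coverage-weighted mean
  of the genome size of every taxon in the profile.  Because each taxon is
  priced at its own (possibly internal-rank) AGS, this estimate does not
  depend on how much eukaryotic or viral DNA the metagenome contains.
* **microbial bases** — predicted bacterial+archaeal base pairs,
  sum of coverage times genome size over all entries.
* **SMF / non-microbial fraction** — microbial bases as a percentage of
  total sequenced bases, capped at 100%, and its complement.
* **known-species fraction** — share of coverage resolved to species rank.
* **per-domain fractions** — e.g. the archaeal share of microbial coverage.

Coverage assigned at the root (unresolved below domain) is still priced at
the root AGS and counted as microbial: marker-recruited reads are
bacterial/archaeal by construction even when their taxonomy is unresolved.
"""

from __future__ import annotations

import csv
import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .profiles import SampleProfile
from .taxonomy import SizeTaxonomy


class EstimateError(ValueError):
    pass


class OverPredictionWarning(UserWarning):
    """Predicted microbial bases exceeded total sequenced bases."""


@dataclass
class SampleEstimate:
    """Derived per-sample statistics; percentages on the 0-100 scale."""

    sample_id: str
    ags: float  # bp
    microbial_bases: float  # bp
    smf: float  # percent of total bases that is microbial
    non_microbial: float  # percent; 100 - smf
    known_species: float  # percent of coverage resolved to species
    domain_fractions: dict[str, float]  # percent of domain-assigned coverage
    ph: float | None = None
    environment: str | None = None


def estimate_ags(profile: SampleProfile, taxonomy: SizeTaxonomy) -> float:
    """Coverage-weighted mean genome size (bp) of the community.

    ``sum_i coverage_i * ags(lineage_i) / sum_i coverage_i`` over all
    profile entries.  Raises on an all-zero-coverage profile.
    """
    total_cov = profile.total_coverage
    if total_cov <= 0:
        raise EstimateError(
            f"sample {profile.sample_id}: no positive coverage; AGS undefined"
        )
    weighted = sum(
        e.coverage * taxonomy.lookup_ags(e.lineage) for e in profile.entries
    )
    return weighted / total_cov


def microbial_bases(profile: SampleProfile, taxonomy: SizeTaxonomy) -> float:
    """Predicted bacterial+archaeal base pairs: sum of coverage x genome size."""
    return sum(e.coverage * taxonomy.lookup_ags(e.lineage) for e in profile.entries)


def smf(profile: SampleProfile, taxonomy: SizeTaxonomy) -> float:
    """Microbial fraction of the metagenome, percent of total bases.

    Capped at 100% (coverage noise can push predicted microbial bases above
    the sequenced total); the cap triggers :class:`OverPredictionWarning`.
    """
    if profile.total_bases <= 0:
        raise EstimateError(f"sample {profile.sample_id}: total_bases must be > 0")
    predicted = microbial_bases(profile, taxonomy)
    pct = 100.0 * predicted / profile.total_bases
    if pct > 100.0:
        # warn only for genuine over-prediction, not float round-off
        if pct > 100.0 * (1.0 + 1e-9):
            warnings.warn(
                f"sample {profile.sample_id}: predicted microbial bases "
                f"({predicted:.3g}) exceed total bases ({profile.total_bases:.3g}); "
                "microbial fraction capped at 100%",
                OverPredictionWarning,
                stacklevel=2,
            )
        pct = 100.0
    return pct


def known_species_fraction(profile: SampleProfile) -> float:
    """Percent of total coverage resolved to species rank."""
    total_cov = profile.total_coverage
    if total_cov <= 0:
        raise EstimateError(
            f"sample {profile.sample_id}: zero total coverage"
        )
    species_cov = sum(e.coverage for e in profile.entries if e.lineage.is_species)
    return 100.0 * species_cov / total_cov


def domain_fraction(profile: SampleProfile, domain_name: str) -> float:
    """Percent of domain-assigned coverage under ``domain_name``.

    Root-level (depth-0) coverage is excluded from numerator and
    denominator.  ``domain_name`` is the prefixed label, e.g.
    ``"d__Archaea"``.
    """
    domain_cov = sum(e.coverage for e in profile.entries if e.lineage.depth >= 1)
    if domain_cov <= 0:
        raise EstimateError(
            f"sample {profile.sample_id}: no coverage assigned at domain rank or below"
        )
    named = sum(
        e.coverage
        for e in profile.entries
        if e.lineage.depth >= 1 and e.lineage.name_at(1) == domain_name
    )
    return 100.0 * named / domain_cov


def estimate_sample(profile: SampleProfile, taxonomy: SizeTaxonomy) -> SampleEstimate:
    """All per-sample statistics for one profile."""
    try:
        ags = estimate_ags(profile, taxonomy)
        mb = microbial_bases(profile, taxonomy)
        smf_pct = smf(profile, taxonomy)
        known = known_species_fraction(profile)
        domains = sorted(
            {e.lineage.name_at(1) for e in profile.entries if e.lineage.depth >= 1}
        )
        fractions = {d: domain_fraction(profile, d) for d in domains}
    except EstimateError as exc:
        raise EstimateError(f"sample {profile.sample_id}: {exc}") from exc
    return SampleEstimate(
        sample_id=profile.sample_id,
        ags=ags,
        microbial_bases=mb,
        smf=smf_pct,
        non_microbial=100.0 - smf_pct,
        known_species=known,
        domain_fractions=fractions,
        ph=profile.ph,
        environment=profile.environment,
    )


def estimate_all(
    profiles: Iterable[SampleProfile], taxonomy: SizeTaxonomy
) -> list[SampleEstimate]:
    """Per-sample estimates for a dataset, ordered by sample id."""
    profiles = list(profiles)
    if not profiles:
        raise EstimateError("no samples to estimate")
    return [
        estimate_sample(p, taxonomy)
        for p in sorted(profiles, key=lambda p: p.sample_id)
    ]


def summarize(estimates: Sequence[SampleEstimate]) -> dict[str, float]:
    """Dataset-level mean and median of the key per-sample statistics."""
    if not estimates:
        raise EstimateError("no estimates to summarize")
    out: dict[str, float] = {"n_samples": float(len(estimates))}
    for name, values in (
        ("ags_mbp", [e.ags / 1e6 for e in estimates]),
        ("smf_pct", [e.smf for e in estimates]),
        ("non_microbial_pct", [e.non_microbial for e in estimates]),
        ("known_species_pct", [e.known_species for e in estimates]),
        ("archaea_pct", [e.domain_fractions.get("d__Archaea", 0.0) for e in estimates]),
    ):
        out[f"mean_{name}"] = statistics.fmean(values)
        out[f"median_{name}"] = statistics.median(values)
    return out


ESTIMATE_COLUMNS = (
    "sample",
    "ags_mbp",
    "microbial_bases_bp",
    "smf_pct",
    "non_microbial_pct",
    "known_species_pct",
    "archaea_pct",
    "bacteria_pct",
)


def write_estimates(
    estimates: Sequence[SampleEstimate],
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write per-sample estimates CSV and, optionally, a summary CSV.

    The per-sample table keeps full float precision (it feeds the
    association stage); the summary table is the human-facing report and
    rounds Mbp to one decimal and percentages to two.
    """
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ESTIMATE_COLUMNS)
        for est in estimates:
            writer.writerow(
                [
                    est.sample_id,
                    repr(est.ags / 1e6),
                    repr(est.microbial_bases),
                    repr(est.smf),
                    repr(est.non_microbial),
                    repr(est.known_species),
                    repr(est.domain_fractions.get("d__Archaea", 0.0)),
                    repr(est.domain_fractions.get("d__Bacteria", 0.0)),
                ]
            )
    if summary_path is not None:
        stats = summarize(estimates)
        with Path(summary_path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["statistic", "value"])
            writer.writerow(["n_samples", int(stats["n_samples"])])
            for key, value in stats.items():
                if key == "n_samples":
                    continue
                digits = 1 if key.endswith("ags_mbp") else 2
                writer.writerow([key, round(value, digits)])
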