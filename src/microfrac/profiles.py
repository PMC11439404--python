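"""Per-sample taxonomic coverage profiles and their I/O.

A profile assigns fold-coverage to lineages at whatever rank the profiler
could resolve (a "condensed" profile): bases attributable to a taxon equal
its coverage times its genome size.  Each sample additionally carries the
total number of sequenced base pairs in the metagenome, which is the
denominator of the microbial fraction.

Sequencing runs belonging to one biological sample are merged at the
coverage level: coverages are additive across runs of the same sample, as
are total base counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .lineage import Lineage, LineageError


class ProfileError(ValueError):
    """Malformed profile/metadata input."""


@dataclass(frozen=True)
class ProfileEntry:
    lineage: Lineage
    coverage: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ProfileError(f"coverage must be >= 0, got {self.coverage}")


@dataclass
class SampleProfile:
    """Taxonomic coverage profile of one metagenome sample."""

    sample_id: str
    entries: list[ProfileEntry]
    total_bases: float
    ph: float | None = None
    environment: str | None = None

    def __post_init__(self) -> None:
        if self.total_bases <= 0:
            raise ProfileError(
                f"sample {self.sample_id}: total_bases must be > 0"
            )
        lineages = [str(e.lineage) for e in self.entries]
        if len(set(lineages)) != len(lineages):
            dupes = sorted({l for l in lineages if lineages.count(l) > 1})
            raise ProfileError(
                f"sample {self.sample_id}: duplicate lineages {dupes}"
            )

    @property
    def total_coverage(self) -> float:
        return sum(e.coverage for e in self.entries)


@dataclass
class _MetadataRow:
    total_bases: float
    ph: float | None = None
    environment: str | None = None
    used: bool = field(default=False, repr=False)


def _read_metadata(path: Path) -> dict[str, _MetadataRow]:
    rows: dict[str, _MetadataRow] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample" not in reader.fieldnames:
            raise ProfileError(f"{path}: metadata must have a 'sample' column")
        cols = set(reader.fieldnames)
        has_total = "total_bases" in cols
        has_counts = {"read_count", "mean_read_length"} <= cols
        if not has_total and not has_counts:
            raise ProfileError(
                f"{path}: metadata needs 'total_bases' or both "
                "'read_count' and 'mean_read_length'"
            )
        for lineno, row in enumerate(reader, start=2):
            sample = row["sample"]
            if sample in rows:
                raise ProfileError(f"{path}:{lineno}: duplicate sample {sample!r}")
            try:
                if has_total and row.get("total_bases", "").strip():
                    total = float(row["total_bases"])
                elif has_counts:
                    total = float(row["read_count"]) * float(row["mean_read_length"])
                else:
                    raise ProfileError("missing total_bases")
                ph_str = (row.get("ph") or "").strip()
                env = (row.get("environment") or "").strip() or None
                rows[sample] = _MetadataRow(
                    total_bases=total,
                    ph=float(ph_str) if ph_str else None,
                    environment=env,
                )
            except (ValueError, ProfileError) as exc:
                raise ProfileError(f"{path}:{lineno}: {exc}") from exc
    return rows


def read_profiles(
    profile_tsv: str | Path, sample_metadata_tsv: str | Path
) -> list[SampleProfile]:
    """Read per-sample coverage profiles plus sample metadata.

    ``profile_tsv`` columns: sample, lineage, coverage (tab-delimited, with
    header).  ``sample_metadata_tsv`` columns: sample, total_bases
    (alternatively read_count and mean_read_length), optional ph and
    environment.  Zero-coverage rows are dropped; duplicate
    (sample, lineage) rows and samples lacking metadata are errors.
    Profiles are returned sorted by sample id.
    """
    profile_tsv = Path(profile_tsv)
    metadata = _read_metadata(Path(sample_metadata_tsv))

    per_sample: dict[str, dict[str, ProfileEntry]] = {}
    with profile_tsv.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "lineage", "coverage"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ProfileError(
                f"{profile_tsv}: profile table must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            sample = row["sample"]
            try:
                lineage = Lineage.parse(row["lineage"])
                coverage = float(row["coverage"])
                if coverage < 0:
                    raise ProfileError(f"negative coverage {coverage}")
            except (LineageError, ValueError, ProfileError) as exc:
                raise ProfileError(f"{profile_tsv}:{lineno}: {exc}") from exc
            if coverage == 0:
                continue
            entries = per_sample.setdefault(sample, {})
            key = str(lineage)
            if key in entries:
                raise ProfileError(
                    f"{profile_tsv}:{lineno}: duplicate entry for sample "
                    f"{sample!r}, lineage {key!r}"
                )
            entries[key] = ProfileEntry(lineage=lineage, coverage=coverage)

    profiles: list[SampleProfile] = []
    for sample in sorted(per_sample):
        meta = metadata.get(sample)
        if meta is None:
            raise ProfileError(
                f"sample {sample!r} has profile rows but no metadata row "
                f"in {sample_metadata_tsv}"
            )
        profiles.append(
            SampleProfile(
                sample_id=sample,
                entries=[per_sample[sample][k] for k in sorted(per_sample[sample])],
                total_bases=meta.total_bases,
                ph=meta.ph,
                environment=meta.environment,
            )
        )
    return profiles


def write_profiles(
    profiles: Iterable[SampleProfile],
    profile_tsv: str | Path,
    sample_metadata_tsv: str | Path | None = None,
) -> None:
    """Write profiles (and optionally sample metadata) as TSV."""
    profiles = list(profiles)
    with Path(profile_tsv).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "lineage", "coverage"])
        for prof in profiles:
            for entry in prof.entries:
                writer.writerow([prof.sample_id, str(entry.lineage), repr(entry.coverage)])
    if sample_metadata_tsv is not None:
        with Path(sample_metadata_tsv).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample", "total_bases", "ph", "environment"])
            for prof in profiles:
                writer.writerow(
                    [
                        prof.sample_id,
                        repr(prof.total_bases),
                        "" if prof.ph is None else repr(prof.ph),
                        prof.environment or "",
                    ]
                )


def merge_runs(
    run_profiles: Iterable[SampleProfile], run_to_sample: Mapping[str, str]
) -> list[SampleProfile]:
    """Merge run-level profiles into sample-level profiles.

    Coverages are summed per lineage across the runs of each sample and
    total base counts are summed; merging a single run is the identity.
    Every run id must appear in ``run_to_sample``.  pH/environment metadata
    must agree across the runs of a sample (first non-null value wins; a
    conflict is an error).
    """
    merged_cov: dict[str, dict[str, float]] = {}
    merged_lineage: dict[str, dict[str, Lineage]] = {}
    merged_total: dict[str, float] = {}
    merged_meta: dict[str, dict[str, object]] = {}

    for run in run_profiles:
        if run.sample_id not in run_to_sample:
            raise ProfileError(f"run {run.sample_id!r} missing from run-to-sample mapping")
        sample = run_to_sample[run.sample_id]
        cov = merged_cov.setdefault(sample, {})
        lins = merged_lineage.setdefault(sample, {})
        for entry in run.entries:
            key = str(entry.lineage)
            cov[key] = cov.get(key, 0.0) + entry.coverage
            lins[key] = entry.lineage
        merged_total[sample] = merged_total.get(sample, 0.0) + run.total_bases
        meta = merged_meta.setdefault(sample, {"ph": None, "environment": None})
        for field_name, value in (("ph", run.ph), ("environment", run.environment)):
            if value is None:
                continue
            if meta[field_name] is None:
                meta[field_name] = value
            elif meta[field_name] != value:
                raise ProfileError(
                    f"sample {sample!r}: conflicting {field_name} across runs"
                )

    return [
        SampleProfile(
            sample_id=sample,
            entries=[
                ProfileEntry(lineage=merged_lineage[sample][k], coverage=v)
                for k, v in sorted(merged_cov[sample].items())
            ],
            total_bases=merged_total[sample],
            ph=merged_meta[sample]["ph"],  # type: ignore[arg-type]
            environment=merged_meta[sample]["environment"],  # type: ignore[arg-type]
        )
        for sample in sorted(merged_cov)
    ]
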