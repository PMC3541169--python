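"""Genome annotation cohorts: data model, TSV I/O, validation and reported fixtures.

A cohort is a table of genomes, one row each, carrying taxonomy, per-family
gene counts for the eight carbohydrate-active-enzyme (CAZy) families involved
in peptidoglycan (PG) metabolism, a three-valued literature PG status
(present / absent / unknown) and optional covariates (lifestyle, GC%, genome
size).  Everything downstream — the 3-gene-set classifier, association
statistics, phylogenetic event analysis — consumes this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "FAMILIES",
    "DOMAINS",
    "PG_STATUSES",
    "LIFESTYLES",
    "SchemaError",
    "ValidationError",
    "GenomeRecord",
    "Cohort",
    "PresenceProfile",
    "binarize",
    "read_cohort",
    "write_cohort",
    "fixture_table1",
    "fixture_confusion_counts",
]

#: The eight CAZy families screened for PG metabolic capacity.
#: GT28 synthesizes GlcNAc-MurNAc dimers, GT51 polymerizes the glycan strand,
#: the GH families lyse PG.
FAMILIES = ("GT28", "GT51", "GH23", "GH25", "GH73", "GH102", "GH103", "GH104")

DOMAINS = ("Bacteria", "Archaea", "Eukaryota", "Viruses")
PG_STATUSES = ("present", "absent", "unknown")
LIFESTYLES = ("free_living", "obligate_intracellular", "other")

# Spellings accepted on input; canonical values are the tuples above.
_DOMAIN_ALIASES = {
    "bacteria": "Bacteria",
    "archaea": "Archaea",
    "archae": "Archaea",
    "eukaryota": "Eukaryota",
    "eukarya": "Eukaryota",
    "eukaryotes": "Eukaryota",
    "viruses": "Viruses",
    "virus": "Viruses",
}
# "ND = not determined" is the convention used in genome-annotation tables.
_PG_ALIASES = {
    "present": "present",
    "+": "present",
    "yes": "present",
    "absent": "absent",
    "-": "absent",
    "no": "absent",
    "unknown": "unknown",
    "nd": "unknown",
    "na": "unknown",
    "n/a": "unknown",
    "": "unknown",
}
_LIFESTYLE_ALIASES = {
    "free_living": "free_living",
    "free-living": "free_living",
    "free living": "free_living",
    "obligate_intracellular": "obligate_intracellular",
    "obligate intracellular": "obligate_intracellular",
    "intracellular": "obligate_intracellular",
    "other": "other",
}

# Default covariate binarization cut-offs used by the PG-absence regression:
# low GC, reduced genome, intracellular lifestyle.
GC_CUTOFF_PERCENT = 50.0
GENOME_SIZE_CUTOFF_MB = 1.5

REQUIRED_COLUMNS = ("genome_id", "domain", "phylum") + FAMILIES + ("pg_status",)
OPTIONAL_COLUMNS = ("lifestyle", "gc_percent", "genome_size_mb")


class SchemaError(ValueError):
    """A table does not have the expected columns."""


class ValidationError(ValueError):
    """A table or record has structurally valid columns but invalid content."""


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: identifiers, taxonomy, gene counts, PG status, covariates."""

    genome_id: str
    domain: str
    phylum: str
    family_counts: Mapping[str, int]
    pg_status: str
    lifestyle: str | None = None
    gc_percent: float | None = None
    genome_size_mb: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")
        if self.pg_status not in PG_STATUSES:
            raise ValidationError(f"unknown pg_status {self.pg_status!r}")
        if self.lifestyle is not None and self.lifestyle not in LIFESTYLES:
            raise ValidationError(f"unknown lifestyle {self.lifestyle!r}")
        missing = [f for f in FAMILIES if f not in self.family_counts]
        if missing:
            raise ValidationError(
                f"genome {self.genome_id!r}: missing family counts for {missing}"
            )
        for fam, count in self.family_counts.items():
            if fam not in FAMILIES:
                raise ValidationError(f"unknown family {fam!r}")
            if not isinstance(count, int) or count < 0:
                raise ValidationError(
                    f"genome {self.genome_id!r}: count for {fam} must be a "
                    f"non-negative integer, got {count!r}"
                )
        if self.gc_percent is not None and not (0.0 <= self.gc_percent <= 100.0):
            raise ValidationError(
                f"genome {self.genome_id!r}: gc_percent outside [0, 100]"
            )
        if self.genome_size_mb is not None and self.genome_size_mb <= 0:
            raise ValidationError(
                f"genome {self.genome_id!r}: genome_size_mb must be positive"
            )
        object.__setattr__(self, "family_counts", dict(self.family_counts))


@dataclass(frozen=True)
class PresenceProfile:
    """Binary presence per family, derived from counts (present = count >= 1)."""

    presence: Mapping[str, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "presence", dict(self.presence))

    def __getitem__(self, family: str) -> bool:
        return self.presence[family]


@dataclass
class Cohort:
    """An ordered collection of genome records with unique identifiers."""

    records: list[GenomeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.genome_id in seen:
                raise ValidationError(f"duplicate genome_id {rec.genome_id!r}")
            seen.add(rec.genome_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, GenomeRecord]:
        return {rec.genome_id: rec for rec in self.records}

    def subset(self, predicate) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)], self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "genome_id": r.genome_id,
                "domain": r.domain,
                "phylum": r.phylum,
            }
            row.update({f: r.family_counts[f] for f in FAMILIES})
            row["pg_status"] = r.pg_status
            row["lifestyle"] = "" if r.lifestyle is None else r.lifestyle
            row["gc_percent"] = "" if r.gc_percent is None else repr(r.gc_percent)
            row["genome_size_mb"] = (
                "" if r.genome_size_mb is None else repr(r.genome_size_mb)
            )
            rows.append(row)
        cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


def binarize(record: GenomeRecord) -> PresenceProfile:
    """Convert gene counts to presence flags: a family is present iff count >= 1.

    Gene-count tables report copy numbers; the screening logic only asks whether
    at least one gene of the family is encoded, so any positive count is
    presence.  The mapping is invariant under rescaling counts by a positive
    integer.
    """
    return PresenceProfile({f: record.family_counts[f] >= 1 for f in FAMILIES})


def _parse_count(value: object, column: str, genome_id: str) -> int:
    text = str(value).strip()
    try:
        n = int(text)
    except (TypeError, ValueError):
        raise ValidationError(
            f"genome {genome_id!r}: malformed count {value!r} in column {column}"
        ) from None
    if n < 0:
        raise ValidationError(
            f"genome {genome_id!r}: negative count {n} in column {column}"
        )
    return n


def _normalize(value: object, aliases: Mapping[str, str], what: str, gid: str) -> str:
    key = str(value).strip().lower()
    if key in aliases:
        return aliases[key]
    raise ValidationError(f"genome {gid!r}: unrecognized {what} {value!r}")


def _optional_float(value: object) -> float | None:
    text = str(value).strip()
    if text == "" or text.lower() in {"nan", "na", "nd"}:
        return None
    return float(text)


def read_cohort(path, dialect: Mapping[str, str] | None = None) -> Cohort:
    """Read an annotation cohort from a tab-delimited UTF-8 table.

    The header must name ``genome_id``, ``domain``, ``phylum``, the eight
    family-count columns and ``pg_status``; ``lifestyle``, ``gc_percent`` and
    ``genome_size_mb`` are optional.  ``dialect`` maps canonical column names to
    the names actually used in the file.  Column order is free.

    ``pg_status`` accepts the aliases ``ND``/``NA``/empty for ``unknown`` and
    ``+``/``-`` for present/absent; unknown status is preserved, never coerced.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (dialect or {}).items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records = []
    for _, row in frame.iterrows():
        gid = str(row["genome_id"]).strip()
        if not gid:
            raise ValidationError("empty genome_id")
        lifestyle = None
        if "lifestyle" in frame.columns and str(row["lifestyle"]).strip():
            lifestyle = _normalize(row["lifestyle"], _LIFESTYLE_ALIASES, "lifestyle", gid)
        records.append(
            GenomeRecord(
                genome_id=gid,
                domain=_normalize(row["domain"], _DOMAIN_ALIASES, "domain", gid),
                phylum=str(row["phylum"]).strip() or "Unclassified",
                family_counts={f: _parse_count(row[f], f, gid) for f in FAMILIES},
                pg_status=_normalize(row["pg_status"], _PG_ALIASES, "pg_status", gid),
                lifestyle=lifestyle,
                gc_percent=_optional_float(row["gc_percent"])
                if "gc_percent" in frame.columns
                else None,
                genome_size_mb=_optional_float(row["genome_size_mb"])
                if "genome_size_mb" in frame.columns
                else None,
            )
        )
    return Cohort(records, provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as a canonical tab-delimited UTF-8 table."""
    cohort.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Printed fixtures: the per-phylum distribution table and the confusion counts
# of the published screening, stored exactly as reported for use in tests and
# worked examples.
# ---------------------------------------------------------------------------

# (group, phylum-or-None, n, GT28, GT51, GH23, GH25, GH73, GH102, GH103, GH104,
#  complete_set).  Domain rows first, then the 21 bacterial phyla plus the
# unclassified remainder, all as reported.
_TABLE1_ROWS = [
    ("Archaea", None, 101, 4, 0, 0, 1, 1, 0, 0, 0, 0),
    ("Viruses", None, 103, 0, 0, 2, 1, 0, 0, 0, 0, 0),
    ("Eukaryota", None, 42, 5, 2, 3, 5, 0, 0, 1, 0, 1),
    ("Bacteria", None, 1398, 1342, 1284, 1224, 419, 707, 467, 528, 95, 1260),
    ("Bacteria", "Actinobacteria", 136, 134, 135, 130, 77, 8, 0, 0, 0, 133),
    ("Bacteria", "Aquificae", 9, 9, 9, 9, 0, 3, 0, 0, 0, 9),
    ("Bacteria", "Bacteroides-Chlorobi", 59, 58, 59, 53, 25, 40, 0, 0, 0, 57),
    ("Bacteria", "Chlamydia", 27, 27, 0, 0, 0, 0, 0, 0, 0, 0),
    ("Bacteria", "Chloroflexi", 14, 9, 9, 9, 1, 0, 0, 0, 0, 9),
    ("Bacteria", "Cyanobacteria", 42, 42, 40, 32, 2, 7, 19, 0, 23, 32),
    ("Bacteria", "Deferribacteres", 3, 3, 3, 3, 0, 0, 0, 3, 0, 3),
    ("Bacteria", "Deinococcus-Thermus", 13, 13, 13, 10, 0, 0, 0, 0, 0, 10),
    ("Bacteria", "Dictyoglomi", 2, 2, 2, 0, 0, 0, 0, 0, 0, 0),
    ("Bacteria", "Elusimicrobia", 2, 2, 2, 1, 0, 0, 0, 0, 0, 1),
    ("Bacteria", "Fibrobacteres-Acidobacteria", 7, 6, 6, 7, 0, 2, 0, 0, 0, 6),
    ("Bacteria", "Firmicutes", 318, 315, 314, 264, 189, 256, 0, 0, 0, 309),
    ("Bacteria", "Fusobacteria", 5, 5, 5, 3, 3, 2, 0, 0, 0, 5),
    ("Bacteria", "Nitrospirae", 2, 2, 2, 2, 0, 0, 0, 0, 0, 2),
    ("Bacteria", "Planctomycetes", 6, 3, 0, 0, 0, 0, 1, 0, 0, 0),
    ("Bacteria", "Proteobacteria", 673, 664, 644, 658, 121, 370, 442, 524, 72, 644),
    ("Bacteria", "Spirochaetes", 27, 27, 26, 26, 1, 11, 4, 0, 0, 26),
    ("Bacteria", "Synergistetes", 3, 3, 2, 3, 0, 0, 0, 0, 0, 2),
    ("Bacteria", "Tenericutes", 32, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    ("Bacteria", "Thermotogae", 11, 11, 10, 10, 0, 8, 0, 0, 0, 10),
    ("Bacteria", "Verrucomicrobia", 4, 4, 1, 2, 0, 0, 0, 0, 0, 0),
    ("Bacteria", "Unclassified", 3, 3, 2, 2, 0, 0, 1, 1, 0, 2),
]


def fixture_table1() -> pd.DataFrame:
    """Per-domain and per-phylum gene-family distribution, as reported.

    Returns a DataFrame with one row per domain (``phylum`` is NA) and one row
    per bacterial phylum, giving the number of genomes (``n``), the number of
    genomes encoding each family, and the number carrying the complete
    3-gene set.  Values are stored exactly as reported; the per-phylum
    ``complete_set`` column does not reconcile perfectly with the domain-level
    total (a known internal inconsistency of the source table), and no
    reconciliation is attempted here.
    """
    cols = ["group", "phylum", "n", *FAMILIES, "complete_set"]
    return pd.DataFrame(_TABLE1_ROWS, columns=cols)


def fixture_confusion_counts() -> dict[str, int]:
    """Named confusion-structure constants of the published screening.

    1,260 of 1,398 bacteria carry the complete 3-gene set (all with literature-
    confirmed PG); the 138 set-negative genomes split into 84 PG-absent,
    24 PG-present and 30 of unknown status; 114 bacteria lack GT51, of which
    5 have PG.
    """
    return {
        "set_positive_total": 1260,
        "set_negative_total": 138,
        "set_negative_pg_absent": 84,
        "set_negative_pg_present": 24,
        "set_negative_pg_unknown": 30,
        "gt51_negative_total": 114,
        "gt51_negative_pg_present": 5,
    }


def fixture_cohort() -> Cohort:
    """Synthetic per-genome cohort consistent with every reported confusion count.

    The published per-genome supplementary tables are not deposited, so this
    builds a deterministic synthetic stand-in cohort of 1,398 bacteria whose
    cross-tabulations reproduce the reported constants exactly:

    * 1,260 genomes with the complete 3-gene set, all PG-present;
    * 138 set-negative genomes: 84 PG-absent (all lacking GT51), 24 PG-present
      (5 lacking GT51, 19 carrying GT51 but no focal GH), 30 unknown
      (25 lacking GT51, 5 carrying it);
    * hence 114 GT51-negative genomes, 5 of them PG-present.

    Gene counts are minimal (0/1); phylum is a generic label.  This is an
    input fixture for the diagnostic-metric computations, not real data.
    """
    counts_full = {f: 1 if f != "GH25" else 0 for f in FAMILIES}
    counts_no_gt51 = dict(counts_full, GT51=0)
    counts_no_gh = {
        f: 1 if f in ("GT28", "GT51") else 0 for f in FAMILIES
    }

    records = []
    idx = 0

    def add(n, counts, pg):
        nonlocal idx
        for _ in range(n):
            idx += 1
            records.append(
                GenomeRecord(
                    genome_id=f"B{idx:04d}",
                    domain="Bacteria",
                    phylum="SyntheticPhylum",
                    family_counts=counts,
                    pg_status=pg,
                )
            )

    add(1260, counts_full, "present")       # complete set, PG confirmed
    add(84, counts_no_gt51, "absent")       # set-negative, PG-less, GT51-less
    add(5, counts_no_gt51, "present")       # GT51-less yet PG-producing
    add(19, counts_no_gh, "present")        # GT51 present but no focal GH
    add(25, counts_no_gt51, "unknown")      # status unknown, GT51-less
    add(5, counts_no_gh, "unknown")         # status unknown, GT51 present
    return Cohort(records, provenance="synthetic fixture cohort (reported counts)")
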