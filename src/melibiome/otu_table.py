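"""OTU count tables: data model, I/O, taxonomic filters, and rarefaction.

The count table is the universal currency between analysis stages: a
non-negative integer matrix with samples as rows and OTUs (97%-identity
16S phylotypes) as columns, carrying one Greengenes-style taxonomy
lineage per OTU.  On disk the canonical format is a tab-separated table
with OTUs as rows (first column the OTU id, last column the lineage);
a BIOM v1 (JSON dialect) reader is provided for interoperability.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyLineage",
    "OtuTable",
    "SampleType",
    "Population",
    "Plant",
    "SampleMetadata",
    "TaxonRule",
    "UNASSIGNED",
    "CHLOROPLAST_RULES",
    "MITOCHONDRIA_RULES",
    "WOLBACHIA_RULES",
    "OtuTableError",
    "RarefactionResult",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "filter_taxa",
    "filter_rare_otus",
    "rarefy",
    "relative_abundance",
]

# Canonical Greengenes rank prefixes, kingdom to species.
_RANK_ORDER = ("k", "p", "c", "o", "f", "g", "s")
_RANK_NAMES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_NAME_TO_PREFIX = {v: k for k, v in _RANK_NAMES.items()}


class OtuTableError(ValueError):
    """Structured error for malformed tables or invalid operations."""


@dataclass(frozen=True)
class TaxonomyLineage:
    """A parsed Greengenes-style lineage, e.g. ``k__Bacteria; p__Proteobacteria``.

    ``ranks`` is the ordered list of ``(rank_prefix, name)`` pairs actually
    present; ``raw`` preserves the original string so parsing round-trips.
    """

    ranks: tuple[tuple[str, str], ...]
    raw: str

    @classmethod
    def parse(cls, raw: str) -> "TaxonomyLineage":
        ranks: list[tuple[str, str]] = []
        text = raw.strip()
        if text and text.lower() not in ("unassigned", "unclassified"):
            last_idx = -1
            for token in text.split(";"):
                token = token.strip()
                if not token:
                    continue
                if len(token) >= 3 and token[1:3] == "__" and token[0] in _RANK_ORDER:
                    prefix, name = token[0], token[3:].strip()
                else:
                    raise OtuTableError(f"unparseable lineage token {token!r} in {raw!r}")
                idx = _RANK_ORDER.index(prefix)
                if idx <= last_idx:
                    raise OtuTableError(
                        f"rank prefix {prefix!r} out of canonical order in {raw!r}"
                    )
                last_idx = idx
                if name:
                    ranks.append((prefix, name))
        return cls(ranks=tuple(ranks), raw=raw)

    def serialize(self) -> str:
        return self.raw

    def name_at(self, rank: str) -> str | None:
        """Name at ``rank`` ('genus', 'class', ... or a one-letter prefix)."""
        prefix = _NAME_TO_PREFIX.get(rank, rank)
        for p, name in self.ranks:
            if p == prefix:
                return name
        return None

    @property
    def is_unassigned(self) -> bool:
        """No information beyond kingdom counts as unassigned."""
        return all(p == "k" for p, _ in self.ranks)


@dataclass(frozen=True)
class TaxonRule:
    """Match rule for taxonomic filtering: a rank plus a name (case-insensitive)."""

    rank: str
    name: str

    def matches(self, lineage: TaxonomyLineage) -> bool:
        got = lineage.name_at(self.rank)
        return got is not None and got.lower() == self.name.lower()


class _UnassignedRule:
    """Special rule matching lineages with no assignment beyond kingdom."""

    rank = "unassigned"
    name = "unassigned"

    def matches(self, lineage: TaxonomyLineage) -> bool:
        return lineage.is_unassigned

    def __repr__(self) -> str:  # pragma: no cover
        return "UNASSIGNED"


UNASSIGNED = _UnassignedRule()

# The host-DNA filters: 16S primers co-amplify chloroplast and mitochondrial rRNA.
CHLOROPLAST_RULES = (TaxonRule("class", "Chloroplast"),)
MITOCHONDRIA_RULES = (TaxonRule("family", "mitochondria"),)
# Wolbachia is matched at genus level; its order (Rickettsiales) is the fallback
# used only when the lineage lacks a genus rank entirely.
WOLBACHIA_RULES = (TaxonRule("genus", "Wolbachia"),)


def _wolbachia_match(lineage: TaxonomyLineage) -> bool:
    if lineage.name_at("genus") is not None:
        return TaxonRule("genus", "Wolbachia").matches(lineage)
    return TaxonRule("order", "Rickettsiales").matches(lineage)


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with ids and per-OTU taxonomy."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[TaxonomyLineage]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise OtuTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise OtuTableError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        for label, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise OtuTableError(f"duplicate {label} id {x!r}")
                seen.add(x)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(self.taxonomy) != len(self.otu_ids):
            raise OtuTableError("one taxonomy lineage required per OTU")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_samples(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(
            counts=self.counts[idx, :].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            otu_ids=list(self.otu_ids),
            taxonomy=list(self.taxonomy),
        )

    def select_otus(self, keep_mask: np.ndarray) -> "OtuTable":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return OtuTable(
            counts=self.counts[:, keep_mask].copy(),
            sample_ids=list(self.sample_ids),
            otu_ids=[o for o, k in zip(self.otu_ids, keep_mask) if k],
            taxonomy=[t for t, k in zip(self.taxonomy, keep_mask) if k],
        )


class SampleType(str, Enum):
    FRASS = "frass"
    LARVA = "larva"
    PLANT_EPIPHYTE = "plant_epiphyte"
    PLANT_ENDOPHYTE = "plant_endophyte"

    @property
    def is_plant(self) -> bool:
        return self in (SampleType.PLANT_EPIPHYTE, SampleType.PLANT_ENDOPHYTE)


class Population(str, Enum):
    BST = "BST"
    HWR = "HWR"


class Plant(str, Enum):
    ME = "Me"  # Medicago sativa (alfalfa)
    LU = "Lu"  # Lupinus argenteus


@dataclass
class SampleMetadata:
    """Per-sample design covariates and performance outcomes.

    Plant (leaf) samples carry no age, weight or survival; frass and
    whole-caterpillar samples carry the caterpillar's age in days.
    """

    sample_id: str
    sample_type: SampleType
    population: Population | None = None
    plant: Plant | None = None
    age_days: int | None = None
    weight_mg: float | None = None
    survived_15d: bool | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.sample_type.is_plant:
            if any(v is not None for v in (self.age_days, self.weight_mg, self.survived_15d)):
                raise OtuTableError(
                    f"plant sample {self.sample_id!r} must not carry age/weight/survival"
                )
        else:
            if self.age_days is None:
                raise OtuTableError(
                    f"{self.sample_type.value} sample {self.sample_id!r} requires age_days"
                )
        if self.weight_mg is not None and self.weight_mg < 0:
            raise OtuTableError(f"negative weight for sample {self.sample_id!r}")


# ---------------------------------------------------------------------------
# I/O

_TAXONOMY_COL = "taxonomy"


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from ``path``.

    ``tsv``: OTUs as rows; first column the OTU id, last column the
    taxonomy lineage string, intermediate columns one per sample.
    ``biom_json``: the BIOM v1 JSON dialect (dense or sparse).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise OtuTableError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if df.shape[1] < 3:
        raise OtuTableError("TSV needs an OTU id column, >=1 sample, and taxonomy")
    sample_cols = list(df.columns[1:-1])
    seen: set[str] = set()
    for c in sample_cols:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            raise OtuTableError(f"duplicate sample column {base!r}")
        seen.add(base)
    otu_ids = df.iloc[:, 0].tolist()
    taxonomy = [TaxonomyLineage.parse(s) for s in df.iloc[:, -1].fillna("")]
    counts = np.empty((len(sample_cols), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                counts[j, i] = int(cell)
            except (TypeError, ValueError):
                raise OtuTableError(
                    f"non-integer count {cell!r} at OTU row {otu_ids[i]!r}, "
                    f"sample column {col!r}"
                ) from None
    return OtuTable(counts=counts, sample_ids=sample_cols, otu_ids=otu_ids, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the canonical TSV (OTUs as rows, taxonomy as the final column)."""
    path = Path(path)
    data = {"#OTU_ID": table.otu_ids}
    for i, sid in enumerate(table.sample_ids):
        data[sid] = table.counts[i, :]
    data[_TAXONOMY_COL] = [t.serialize() for t in table.taxonomy]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    taxonomy = []
    for r in doc["rows"]:
        tax = (r.get("metadata") or {}).get("taxonomy", "")
        if isinstance(tax, list):
            tax = "; ".join(tax)
        taxonomy.append(TaxonomyLineage.parse(tax))
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)  # rows = OTUs in BIOM
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(v)
    return OtuTable(counts=mat.T, sample_ids=sample_ids, otu_ids=otu_ids, taxonomy=taxonomy)


_META_COLS = [
    "sample_id",
    "sample_type",
    "population",
    "plant",
    "age_days",
    "weight_mg",
    "survived_15d",
    "family_id",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV; empty cells mean absent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise OtuTableError(f"metadata missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        def get(col: str) -> str | None:
            v = row[col]
            return None if pd.isna(v) or v == "" else str(v)

        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                sample_type=SampleType(str(row["sample_type"])),
                population=Population(p) if (p := get("population")) else None,
                plant=Plant(p) if (p := get("plant")) else None,
                age_days=int(a) if (a := get("age_days")) else None,
                weight_mg=float(w) if (w := get("weight_mg")) else None,
                survived_15d=(s in ("1", "True", "true")) if (s := get("survived_15d")) is not None else None,
                family_id=get("family_id"),
            )
        )
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in records:
        rows.append(
            {
                "sample_id": m.sample_id,
                "sample_type": m.sample_type.value,
                "population": m.population.value if m.population else "",
                "plant": m.plant.value if m.plant else "",
                "age_days": "" if m.age_days is None else m.age_days,
                "weight_mg": "" if m.weight_mg is None else m.weight_mg,
                "survived_15d": "" if m.survived_15d is None else int(m.survived_15d),
                "family_id": m.family_id or "",
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters

def filter_taxa(table: OtuTable, exclude: Iterable) -> OtuTable:
    """Drop OTU columns whose lineage matches any rule in ``exclude``.

    Rules are :class:`TaxonRule` instances or the :data:`UNASSIGNED`
    sentinel.  Samples are retained even if their row sum drops to zero;
    OTU order is preserved.  Removing every OTU is an error.
    """
    rules = list(exclude)
    keep = np.ones(table.n_otus, dtype=bool)
    for j, lineage in enumerate(table.taxonomy):
        for rule in rules:
            special_wolbachia = (
                isinstance(rule, TaxonRule)
                and rule.rank in ("genus", "g")
                and rule.name.lower() == "wolbachia"
            )
            hit = _wolbachia_match(lineage) if special_wolbachia else rule.matches(lineage)
            if hit:
                keep[j] = False
                break
    if not keep.any():
        raise OtuTableError("taxonomic filter removed every OTU")
    return table.select_otus(keep)


def filter_rare_otus(table: OtuTable, min_rel_abund: float = 0.01) -> OtuTable:
    """Drop OTUs whose relative abundance is below ``min_rel_abund`` in every sample.

    An OTU is retained iff its within-sample relative abundance reaches the
    threshold in at least one sample.  Zero-sum samples contribute no
    retention votes (warned, not fatal).
    """
    if not 0 <= min_rel_abund < 1:
        raise OtuTableError("min_rel_abund must be in [0, 1)")
    if min_rel_abund == 0:
        return table
    totals = table.sample_sums().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero total excluded from rare-OTU votes",
            stacklevel=2,
        )
    totals[zero] = 1.0  # avoid div-by-zero; zero rows have all-zero rel abund anyway
    rel = table.counts / totals[:, None]
    keep = (rel >= min_rel_abund).any(axis=0)
    if not keep.any():
        raise OtuTableError("rare-OTU filter removed every OTU")
    return table.select_otus(keep)


# ---------------------------------------------------------------------------
# Rarefaction

@dataclass
class RarefactionResult:
    table: OtuTable
    dropped_sample_ids: list[str]


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # One independent stream per sample keyed by (seed, sample id), so that
    # dropping a sample never shifts another sample's draw.
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefy(table: OtuTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample each sample to exactly ``depth`` sequences without replacement.

    Samples with fewer than ``depth`` sequences are dropped and reported
    (a row sum exactly equal to ``depth`` is retained unchanged).  The draw
    is multivariate hypergeometric, i.e. a uniform subsample of the
    sample's existing sequences.
    """
    if depth < 1:
        raise OtuTableError("rarefaction depth must be >= 1")
    totals = table.sample_sums()
    keep = totals >= depth
    dropped = [sid for sid, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise OtuTableError(f"all samples have fewer than {depth} sequences")
    new_counts = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = table.counts[i, :]
        if totals[i] == depth:
            new_counts.append(row.copy())
        else:
            rng = _sample_rng(seed, sid)
            new_counts.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    sub = OtuTable(
        counts=np.asarray(new_counts, dtype=np.int64),
        sample_ids=kept_ids,
        otu_ids=list(table.otu_ids),
        taxonomy=list(table.taxonomy),
    )
    return RarefactionResult(table=sub, dropped_sample_ids=dropped)


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Counts divided by sample totals; every row sums to 1."""
    totals = table.sample_sums().astype(float)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise OtuTableError(f"sample {bad!r} has zero total count")
    return table.counts / totals[:, None]
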