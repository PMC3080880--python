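"""Core containers: sequence records, region maps, and gapped alignments.

The pipeline works on the fungal nuclear ribosomal internal transcribed
spacer (ITS) region, which consists of the hypervariable ITS1 spacer, the
conserved 5.8S rRNA gene, and the hypervariable ITS2 spacer.  A
:class:`SequenceRecord` holds one unaligned DNA sequence together with an
optional taxonomic group label and an optional :class:`RegionMap` locating
the three subregions on the ungapped residues.  A :class:`Msa` is a
rectangular gapped alignment keyed by record id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Reserved label for query sequences whose taxonomic group is unknown.
ENVIRONMENTAL = "environmental"

#: Canonical region names, in 5'->3' order.
REGION_NAMES = ("ITS1", "5.8S", "ITS2")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionMap:
    """0-based half-open intervals of ITS1 / 5.8S / ITS2 on ungapped residues.

    Any of the three intervals may be absent (``None``), e.g. for records
    truncated before the ITS2.  Present intervals must be non-overlapping
    and ordered ITS1 < 5.8S < ITS2.
    """

    its1: tuple[int, int] | None = None
    r58s: tuple[int, int] | None = None
    its2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in (self.its1, self.r58s, self.its2):
            if iv is None:
                continue
            start, end = iv
            if not (0 <= start <= end):
                raise InvalidInputError(f"bad region interval {iv}")
            if start < prev_end:
                raise InvalidInputError(
                    "region intervals must be ordered ITS1 < 5.8S < ITS2 "
                    "and non-overlapping"
                )
            prev_end = end

    def as_dict(self) -> dict[str, tuple[int, int]]:
        out = {}
        for name, iv in zip(REGION_NAMES, (self.its1, self.r58s, self.its2)):
            if iv is not None:
                out[name] = iv
        return out

    @property
    def span_end(self) -> int:
        ends = [iv[1] for iv in (self.its1, self.r58s, self.its2) if iv]
        return max(ends) if ends else 0


@dataclass(frozen=True)
class SequenceRecord:
    """One unaligned DNA sequence.

    ``label`` is either a taxonomic group name (a labelled reference) or
    the reserved value ``"environmental"`` for unidentified query records.
    """

    id: str
    residues: str
    label: str = ENVIRONMENTAL
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidInputError(f"record {self.id!r} has empty residues")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise InvalidInputError(
                f"record {self.id!r} contains non-IUPAC symbols {sorted(bad)}"
            )
        if self.region_map is not None and self.region_map.span_end > len(self.residues):
            raise InvalidInputError(
                f"record {self.id!r}: region map exceeds sequence bounds"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_query(self) -> bool:
        return self.label == ENVIRONMENTAL

    def with_residues(self, residues: str, region_map: RegionMap | None = None) -> "SequenceRecord":
        return replace(self, residues=residues, region_map=region_map)


@dataclass
class Msa:
    """Rectangular gapped alignment, ordered map id -> gapped row."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise InvalidInputError("alignment rows have unequal lengths")
        for rid, row in self.rows.items():
            if set(row) <= {GAP}:
                raise InvalidInputError(f"all-gap row {rid!r}")

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def degap(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())

    def subset(self, ids: Iterable[str], drop_empty_columns: bool = True) -> "Msa":
        ids = list(ids)
        rows = {rid: self.rows[rid] for rid in ids}
        if drop_empty_columns and rows:
            keep = [
                j
                for j in range(self.ncol)
                if any(row[j] != GAP for row in rows.values())
            ]
            rows = {rid: "".join(row[j] for j in keep) for rid, row in rows.items()}
        return Msa(rows)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, labels: Mapping[str, str] | None = None) -> list[SequenceRecord]:
    """Read unaligned records; optional id->group labels (default environmental)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = labels.get(rec.id, ENVIRONMENTAL) if labels else ENVIRONMENTAL
        out.append(SequenceRecord(rec.id, str(rec.seq).upper(), label=label))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_msa_fasta(path: str | Path) -> Msa:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Msa(rows)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    seqs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in msa.rows.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_regions_tsv(path: str | Path) -> dict[str, RegionMap]:
    """Read region annotations (columns: id, region, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "region": str})
    maps: dict[str, RegionMap] = {}
    for rid, sub in df.groupby("id", sort=False):
        kw: dict[str, tuple[int, int]] = {}
        for _, row in sub.iterrows():
            key = {"ITS1": "its1", "5.8S": "r58s", "ITS2": "its2"}[row["region"]]
            kw[key] = (int(row["start"]), int(row["end"]))
        maps[rid] = RegionMap(**kw)
    return maps


def write_regions_tsv(maps: Mapping[str, RegionMap], path: str | Path) -> None:
    rows = []
    for rid, rmap in maps.items():
        for region, (start, end) in rmap.as_dict().items():
            rows.append({"id": rid, "region": region, "start": start, "end": end})
    pd.DataFrame(rows, columns=["id", "region", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["group"]))


def write_groups_tsv(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": k, "group": v} for k, v in labels.items()], columns=["id", "group"]
    ).to_csv(path, sep="\t", index=False)


def attach(records: Iterable[SequenceRecord],
           region_maps: Mapping[str, RegionMap] | None = None,
           labels: Mapping[str, str] | None = None) -> list[SequenceRecord]:
    """Return records with region maps and/or labels attached by id."""
    out = []
    for rec in records:
        rmap = region_maps.get(rec.id, rec.region_map) if region_maps else rec.region_map
        label = labels.get(rec.id, rec.label) if labels else rec.label
        out.append(replace(rec, region_map=rmap, label=label))
    return out


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
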