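"""ITS region surgery: splitting, constant-anchor splicing, 5.8S re-insertion.

The conserved 5.8S gene can dominate guide-tree construction and drag the
hypervariable ITS1/ITS2 spacers out of register during multiple alignment.
The anchored procedure removes the 5.8S from every record and replaces it
with one short constant segment (16 characters by default) that keeps ITS1
and ITS2 separated during alignment; after the alignment is estimated the
anchor columns are swapped back for the true, separately aligned 5.8S
block.  The two operations are exact inverses on ungapped residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .records import GAP, InvalidInputError, Msa, SequenceRecord

DEFAULT_ANCHOR_LENGTH = 16
# Constant across taxa by construction.  The motif is deliberately
# aperiodic (at most 3/16 self-matches under any shift): a periodic motif
# would let an aligner register two copies of the anchor at a nonzero
# offset without mismatch cost, silently splitting the block.
ANCHOR_MOTIF = "AATGTCCGCTGGACAT"


def default_anchor(length: int = DEFAULT_ANCHOR_LENGTH) -> str:
    reps = (length + len(ANCHOR_MOTIF) - 1) // len(ANCHOR_MOTIF)
    return (ANCHOR_MOTIF * reps)[:length]


@dataclass
class AnchoredSet:
    """Records with residues ITS1 + anchor + ITS2, plus the excised 5.8S."""

    anchored_records: list[SequenceRecord]
    excised: dict[str, str]
    anchor: str
    provenance: dict[str, dict[str, tuple[int, int]]]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def reassemble(self, rid: str) -> str:
        """ITS1 + original 5.8S + ITS2 for one anchored record."""
        rec = next(r for r in self.anchored_records if r.id == rid)
        n1 = rec.region_map.its1[1] - rec.region_map.its1[0]
        its1 = rec.residues[:n1]
        its2 = rec.residues[n1 + len(self.anchor):]
        return its1 + self.excised[rid] + its2


def split_regions(record: SequenceRecord) -> tuple[str, str, str, tuple[str, str]]:
    """Slice a record into (ITS1, 5.8S, ITS2, (left fringe, right fringe)).

    Fringes are residues outside the annotated regions (typically 18S/28S
    remnants left by the PCR primers); they are discarded before any
    alignment strategy.
    """
    if record.region_map is None:
        raise InvalidInputError(f"record {record.id!r} has no region map")
    rmap = record.region_map
    ivs = rmap.as_dict()
    its1 = record.residues[slice(*ivs["ITS1"])] if "ITS1" in ivs else ""
    r58s = record.residues[slice(*ivs["5.8S"])] if "5.8S" in ivs else ""
    its2 = record.residues[slice(*ivs["ITS2"])] if "ITS2" in ivs else ""
    starts = [iv[0] for iv in ivs.values()]
    ends = [iv[1] for iv in ivs.values()]
    left = record.residues[: min(starts)] if starts else record.residues
    right = record.residues[max(ends):] if ends else ""
    # regions must tile the interior contiguously for the fringe identity
    interior = record.residues[min(starts): max(ends)] if starts else ""
    if its1 + r58s + its2 != interior:
        raise InvalidInputError(
            f"record {record.id!r}: regions do not tile the annotated interior"
        )
    return its1, r58s, its2, (left, right)


def make_anchored(records: Iterable[SequenceRecord],
                  anchor_length: int = DEFAULT_ANCHOR_LENGTH) -> AnchoredSet:
    """Replace every record's 5.8S by a shared constant anchor.

    Records lacking an ITS1 or a 5.8S interval cannot be anchored and are
    excluded with a per-record reason rather than failing globally.
    """
    anchor = default_anchor(anchor_length)
    out: list[SequenceRecord] = []
    excised: dict[str, str] = {}
    provenance: dict[str, dict[str, tuple[int, int]]] = {}
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if rec.region_map is None:
            excluded.append((rec.id, "missing_region_map"))
            continue
        if rec.region_map.r58s is None:
            excluded.append((rec.id, "missing_58s"))
            continue
        if rec.region_map.its1 is None or rec.region_map.its1[0] == rec.region_map.its1[1]:
            excluded.append((rec.id, "missing_its1"))
            continue
        its1, r58s, its2, _ = split_regions(rec)
        from .records import RegionMap  # local to avoid cycle at import time

        new_map = RegionMap(
            its1=(0, len(its1)),
            r58s=(len(its1), len(its1) + anchor_length),
            its2=(len(its1) + anchor_length, len(its1) + anchor_length + len(its2)),
        )
        out.append(rec.with_residues(its1 + anchor + its2, region_map=new_map))
        excised[rec.id] = r58s
        provenance[rec.id] = rec.region_map.as_dict()
    return AnchoredSet(out, excised, anchor, provenance, excluded)


def _normalize_anchor(msa: Msa, anchor: str, slack: int = 24) -> tuple[Msa, int]:
    """Canonicalise gap placement around the anchor block.

    Because the anchor's terminal residues can coincide with adjacent ITS
    residues, an optimal alignment may slide a gap across the block
    boundary at no score cost, leaving one row's anchor a column or two
    out of register.  Such variants are score-equivalent, so they are
    normalised here: the consensus anchor start column is taken as the
    mode over rows, and any deviant row is locally rewritten within a
    +/- ``slack`` column window so its anchor occupies exactly the
    consensus block.  Rows whose anchor residues stray beyond the window
    indicate genuine misalignment and raise an internal-consistency error.

    Returns the normalised alignment and the block start column.
    """
    la = len(anchor)
    # anchor residue index and columns per row (an exact chance hit of a
    # 16-mer inside ITS1/ITS2 has probability ~4^-16 per site: negligible)
    anchor_cols: dict[str, list[int]] = {}
    anchor_start_res: dict[str, int] = {}
    for rid, row in msa.rows.items():
        degapped = row.replace(GAP, "")
        a = degapped.find(anchor)
        if a < 0:
            raise InvalidInputError(
                f"anchor absent from row {rid!r}: upstream aligner corrupted it"
            )
        res_cols = [j for j, ch in enumerate(row) if ch != GAP]
        anchor_cols[rid] = res_cols[a:a + la]
        anchor_start_res[rid] = a

    starts = [cols[0] for cols in anchor_cols.values()
              if cols == list(range(cols[0], cols[0] + la))]
    if not starts:
        raise InvalidInputError("no row carries a contiguous anchor block")
    lo = max(set(starts), key=starts.count)

    rows = dict(msa.rows)
    for rid, cols in anchor_cols.items():
        if cols == list(range(lo, lo + la)):
            continue
        row = rows[rid]
        w_lo, w_hi = max(0, lo - slack), min(len(row), lo + la + slack)
        if cols[0] < w_lo or cols[-1] >= w_hi:
            raise InvalidInputError(
                f"anchor in row {rid!r} strays beyond the repair window: "
                "upstream aligner corrupted it"
            )
        a = anchor_start_res[rid]
        res_cols = [j for j, ch in enumerate(row) if ch != GAP]
        # residues inside the window, split around the anchor
        pre = [row[j] for j in res_cols if w_lo <= j < w_hi
               and res_cols.index(j) < a]
        post = [row[j] for j in res_cols if w_lo <= j < w_hi
                and res_cols.index(j) >= a + la]
        if len(pre) > lo - w_lo or len(post) > w_hi - (lo + la):
            raise InvalidInputError(
                f"anchor in row {rid!r} cannot be restored within the repair "
                "window: upstream aligner corrupted it"
            )
        window = (
            [GAP] * (lo - w_lo - len(pre)) + pre + list(anchor)
            + post + [GAP] * (w_hi - lo - la - len(post))
        )
        rows[rid] = row[:w_lo] + "".join(window) + row[w_hi:]
    return Msa(rows), lo


def reinsert_58s(anchored_msa: Msa, excised: Mapping[str, str],
                 aligner: Callable[[Sequence[SequenceRecord]], Msa],
                 anchor: str | None = None) -> Msa:
    """Swap the anchor columns for the aligned true 5.8S block.

    The excised 5.8S substrings are aligned among themselves with the
    supplied aligner (they are conserved, so a single pass suffices); the
    anchor columns are then deleted and the aligned 5.8S block spliced in
    at the same position.  Degapped rows equal the original full residues.
    """
    anchor = anchor or default_anchor()
    anchored_msa, lo = _normalize_anchor(anchored_msa, anchor)
    hi = lo + len(anchor)

    ids = list(anchored_msa.rows)
    missing = [rid for rid in ids if rid not in excised]
    if missing:
        raise InvalidInputError(f"no excised 5.8S for rows {missing}")
    lengths = {len(excised[rid]) for rid in ids}
    seqs = [SequenceRecord(rid, excised[rid]) for rid in ids]
    if len(ids) == 1 or len(lengths) == 1 and len({excised[r] for r in ids}) == 1:
        # identical 5.8S across rows: trivially aligned, no gaps
        block = Msa({rid: excised[rid] for rid in ids})
    else:
        block = aligner(seqs)

    rows = {}
    for rid, row in anchored_msa.rows.items():
        rows[rid] = row[:lo] + block.rows[rid] + row[hi:]
    return Msa(rows)
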