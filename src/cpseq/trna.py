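"""tRNA-fragment taxonomy: halves, tRFs, 3'-half subtypes and His -1 variants.

Coordinates follow canonical tRNA nucleotide-position (np) numbering: np 1 is
the first body nucleotide, np 73 the discriminator, np 74-76 the
post-transcriptionally added CCA. His-type records carry one extra 5'
nucleotide at np -1, so their sequence index 0 maps to np -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd


class FragmentClass(str, Enum):
    FIVE_HALF = "FIVE_HALF"
    THREE_HALF = "THREE_HALF"
    FIVE_TRF = "FIVE_TRF"
    THREE_TRF = "THREE_TRF"
    I_TRF = "I_TRF"


class ThreeHalfSubtype(str, Enum):
    CCA = "CCA"
    CC = "CC"
    C = "C"
    DI = "DI"
    NONE = "none"


class HisVariant(str, Enum):
    G_MINUS1 = "G_minus1"
    U_MINUS1 = "U_minus1"
    G1 = "G1"
    NONE = "none"


@dataclass(frozen=True)
class TRNARecord:
    """A mature tRNA reference with CCA and its np-numbering anchors.

    ``loop_start``/``loop_end`` are 0-based inclusive sequence indices of the
    anticodon loop (np 32-38 by default). ``np1_index`` is the sequence index
    holding np 1 (1 for records with a -1 nucleotide, else 0).
    """

    ref_id: str
    isoacceptor: str
    sequence: str
    loop_start: int
    loop_end: int
    has_minus1: bool = False
    minus1_base: str | None = None

    @property
    def np1_index(self) -> int:
        return 1 if self.has_minus1 else 0

    def np_to_index(self, np: int) -> int:
        if np == -1:
            if not self.has_minus1:
                raise ValueError(f"{self.ref_id} has no -1 nucleotide")
            return 0
        if np < 1:
            raise ValueError(f"invalid np {np}")
        return self.np1_index + np - 1

    def index_to_np(self, idx: int) -> int:
        if idx < 0 or idx >= len(self.sequence):
            raise ValueError(f"index {idx} outside {self.ref_id}")
        if idx < self.np1_index:
            return -1
        return idx - self.np1_index + 1

    @property
    def discriminator_index(self) -> int:
        """Index of np 73."""
        return self.np1_index + 72

    def validate(self) -> None:
        if self.index_to_np(len(self.sequence) - 1) != 76:
            raise ValueError(f"{self.ref_id}: last base must be np 76")
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.ref_id}: mature sequence must end with CCA")
        if self.has_minus1 and self.minus1_base not in ("A", "C", "G", "T", "U"):
            raise ValueError(f"{self.ref_id}: -1 record needs a -1 base")


@dataclass(frozen=True)
class FragmentCall:
    read_id: str
    ref_id: str
    fragment_class: FragmentClass
    three_half_subtype: ThreeHalfSubtype = ThreeHalfSubtype.NONE
    his_variant: HisVariant = HisVariant.NONE
    start: int = 0
    end: int = 0


def classify_fragment(aln, trna: TRNARecord) -> FragmentCall:
    """Assign exactly one fragment class to a tRNA-mapped alignment.

    Precedence: FIVE_HALF > THREE_HALF > FIVE_TRF > THREE_TRF > I_TRF.
    """
    start, end = aln.start, aln.end
    if start < 0 or end > len(trna.sequence) or start >= end:
        raise ValueError(
            f"alignment [{start},{end}) outside reference {trna.ref_id} "
            f"(length {len(trna.sequence)})"
        )
    last = end - 1
    five_anchored = start == trna.np1_index or (trna.has_minus1 and start == 0)
    ends_at_terminus = last >= trna.discriminator_index

    if five_anchored and trna.loop_start <= last <= trna.loop_end:
        cls = FragmentClass.FIVE_HALF
    elif (trna.loop_start <= start <= trna.loop_end + 1) and ends_at_terminus:
        cls = FragmentClass.THREE_HALF
    elif five_anchored and last < trna.loop_start:
        cls = FragmentClass.FIVE_TRF
    elif ends_at_terminus and start > trna.loop_end:
        cls = FragmentClass.THREE_TRF
    else:
        cls = FragmentClass.I_TRF

    subtype = (
        subtype_three_half(aln, trna) if cls is FragmentClass.THREE_HALF else ThreeHalfSubtype.NONE
    )
    variant = HisVariant.NONE
    if trna.has_minus1 and five_anchored:
        variant = call_his_variant(aln, trna)
    return FragmentCall(
        read_id=aln.read_id,
        ref_id=trna.ref_id,
        fragment_class=cls,
        three_half_subtype=subtype,
        his_variant=variant,
        start=start,
        end=end,
    )


def subtype_three_half(aln, trna: TRNARecord) -> ThreeHalfSubtype:
    """3'-half subtype by terminal np: 76 -> CCA, 75 -> CC, 74 -> C, 73 -> DI."""
    last_np = trna.index_to_np(aln.end - 1)
    if last_np == 76:
        return ThreeHalfSubtype.CCA
    if last_np == 75:
        return ThreeHalfSubtype.CC
    if last_np == 74:
        return ThreeHalfSubtype.C
    if last_np == 73:
        return ThreeHalfSubtype.DI
    raise ValueError(f"read {aln.read_id}: 3' end at np {last_np} is not a 3'-half terminus")


def call_his_variant(aln, trna: TRNARecord) -> HisVariant:
    """Classify a 5'-anchored read on a -1-bearing record by its start position."""
    if not trna.has_minus1:
        raise ValueError(f"{trna.ref_id} carries no -1 nucleotide")
    if aln.start == 0:
        base = trna.sequence[0]
        if base == "G":
            return HisVariant.G_MINUS1
        if base in ("T", "U"):
            return HisVariant.U_MINUS1
        return HisVariant.NONE
    if aln.start == trna.np1_index:
        return HisVariant.G1
    return HisVariant.NONE


def isoacceptor_proportions(calls, trna_by_ref: dict[str, TRNARecord]) -> pd.Series:
    """Fraction of 5'-half calls per isoacceptor, sorted descending."""
    five = [c for c in calls if c.fragment_class is FragmentClass.FIVE_HALF]
    if not five:
        raise ValueError("no 5'-half calls to summarize")
    names = [trna_by_ref[c.ref_id].isoacceptor for c in five]
    counts = pd.Series(names).value_counts()
    return (counts / counts.sum()).sort_values(ascending=False)


def class_proportions(calls) -> pd.Series:
    counts = pd.Series([c.fragment_class.value for c in calls]).value_counts()
    return counts / counts.sum()


def three_half_subtype_proportions(calls) -> pd.Series:
    subs = [
        c.three_half_subtype.value for c in calls if c.fragment_class is FragmentClass.THREE_HALF
    ]
    if not subs:
        return pd.Series(dtype=float)
    counts = pd.Series(subs).value_counts()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Annotation table round-trip

ANNOTATION_COLUMNS = [
    "ref_id",
    "isoacceptor",
    "loop_start",
    "loop_end",
    "has_minus1",
    "minus1_base",
]


def write_annotation(path, records: list[TRNARecord]) -> None:
    rows = [
        {
            "ref_id": r.ref_id,
            "isoacceptor": r.isoacceptor,
            "loop_start": r.loop_start,
            "loop_end": r.loop_end,
            "has_minus1": int(r.has_minus1),
            "minus1_base": r.minus1_base or ".",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation(path, sequences: dict[str, str]) -> list[TRNARecord]:
    df = pd.read_csv(path, sep="\t", dtype={"minus1_base": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TRNARecord(
                ref_id=row.ref_id,
                isoacceptor=row.isoacceptor,
                sequence=sequences[row.ref_id],
                loop_start=int(row.loop_start),
                loop_end=int(row.loop_end),
                has_minus1=bool(row.has_minus1),
                minus1_base=None if row.minus1_base == "." else row.minus1_base,
            )
        )
    return records


def write_fragment_calls(path: Path, calls) -> None:
    rows = [
        {
            "read_id": c.read_id,
            "ref_id": c.ref_id,
            "fragment_class": c.fragment_class.value,
            "three_half_subtype": c.three_half_subtype.value,
            "his_variant": c.his_variant.value,
            "start_1based": c.start + 1,
            "end_1based": c.end,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "ref_id",
            "fragment_class",
            "three_half_subtype",
            "his_variant",
            "start_1based",
            "end_1based",
        ],
    ).to_csv(path, sep="\t", index=False)
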