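"""Terminal/flanking nucleotide composition, cleavage-site inference, and
per-substrate alignment profiles — the descriptive analyses that expose a
C|A cleavage signature in fragment termini.

Sequences are handled in the DNA alphabet internally; composition outputs
are reported in the RNA alphabet (U for T) to match figure conventions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cpseq._util import revcomp
from cpseq.mapping import CategoryAlignment
from cpseq.trna import FragmentCall, FragmentClass, TRNARecord

RNA_BASES = ("A", "C", "G", "U")
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U", "U": "U", "N": "N"}


def _empty_matrix(labels) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=labels, columns=list(RNA_BASES))


@dataclass
class CompositionMatrix:
    """Per-position base fractions; index = position labels, columns = A/C/G/U."""

    fractions: pd.DataFrame
    n_reads: int
    counts: pd.DataFrame | None = None

    def fraction(self, position, base: str) -> float:
        return float(self.fractions.loc[position, base])


def _tally(counts: dict, label, base: str) -> None:
    b = _DNA_TO_RNA.get(base)
    if b in RNA_BASES:
        counts[label][b] += 1


def _finalize(counts: dict, labels, n_reads: int) -> CompositionMatrix:
    raw = pd.DataFrame(
        {b: [counts[lab][b] for lab in labels] for b in RNA_BASES}, index=list(labels)
    ).astype(float)
    totals = raw.sum(axis=1)
    frac = raw.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return CompositionMatrix(fractions=frac, n_reads=n_reads, counts=raw)


def end_composition(sequences, end: int, n_positions: int = 30) -> CompositionMatrix:
    """Base composition of the first ``n_positions`` bases from the 5' or 3' end.

    Position p (1-based) counts the p-th base from the chosen end for every
    sequence of length >= p; shorter sequences contribute only to the
    positions they cover.
    """
    if end not in (5, 3):
        raise ValueError("end must be 5 or 3")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    labels = list(range(1, n_positions + 1))
    counts = {lab: dict.fromkeys(RNA_BASES, 0) for lab in labels}
    n = 0
    for seq in sequences:
        n += 1
        m = min(len(seq), n_positions)
        for p in range(1, m + 1):
            base = seq[p - 1] if end == 5 else seq[len(seq) - p]
            _tally(counts, p, base)
    return _finalize(counts, labels, n)


def fragment_sequence(aln: CategoryAlignment, references: dict[str, str]) -> str:
    """Read-orientation sequence of an aligned fragment."""
    seq = references[aln.ref_id][aln.start : aln.end]
    return revcomp(seq) if aln.strand == "-" else seq


def flanking_context(
    assignments, references: dict[str, str], k: int = 4
) -> CompositionMatrix:
    """Reference base composition at positions -k..-1 and +1..+k around fragments.

    -1 is the reference base immediately 5' of the fragment in read
    orientation, +1 immediately 3' of it; minus-strand fragments use the
    reverse complement. Fragments at a reference edge contribute only the
    flanking positions that exist.
    """
    labels = list(range(-k, 0)) + list(range(1, k + 1))
    counts = {lab: dict.fromkeys(RNA_BASES, 0) for lab in labels}
    n = 0
    for aln in assignments:
        if aln.ref_id is None:
            continue
        ref = references[aln.ref_id]
        n += 1
        if aln.strand == "+":
            up = ref[max(0, aln.start - k) : aln.start]  # ends at -1
            down = ref[aln.end : aln.end + k]  # starts at +1
        else:
            up = revcomp(ref[aln.end : aln.end + k])
            down = revcomp(ref[max(0, aln.start - k) : aln.start])
        for offset, base in enumerate(reversed(up)):  # offset 0 -> position -1
            _tally(counts, -(offset + 1), base)
        for offset, base in enumerate(down):
            _tally(counts, offset + 1, base)
    return _finalize(counts, labels, n)


def ca_boundary_fraction(
    assignments, references: dict[str, str]
) -> tuple[float | None, float | None, float | None]:
    """(5'-boundary, 3'-boundary, both) C|A junction fractions.

    A 5' boundary is C|A when the base upstream of the fragment is C and the
    fragment starts with A; a 3' boundary when the fragment ends with C and
    the next reference base is A. Edge fragments are excluded from the
    denominators of the boundaries they lack; None when no fragment
    qualifies.
    """
    n5 = n3 = nb = 0
    hit5 = hit3 = hitb = 0
    for aln in assignments:
        if aln.ref_id is None or aln.start >= aln.end:
            continue
        ref = references[aln.ref_id]
        if aln.strand == "+":
            up = ref[aln.start - 1] if aln.start > 0 else None
            first = ref[aln.start]
            last = ref[aln.end - 1]
            down = ref[aln.end] if aln.end < len(ref) else None
        else:
            up = revcomp(ref[aln.end])[0] if aln.end < len(ref) else None
            first = revcomp(ref[aln.end - 1])[0]
            last = revcomp(ref[aln.start])[0]
            down = revcomp(ref[aln.start - 1])[0] if aln.start > 0 else None
        ok5 = up == "C" and first == "A" if up is not None else None
        ok3 = last == "C" and down == "A" if down is not None else None
        if ok5 is not None:
            n5 += 1
            hit5 += ok5
        if ok3 is not None:
            n3 += 1
            hit3 += ok3
        if ok5 is not None and ok3 is not None:
            nb += 1
            hitb += ok5 and ok3
    return (
        hit5 / n5 if n5 else None,
        hit3 / n3 if n3 else None,
        hitb / nb if nb else None,
    )


@dataclass
class CleavageProfile:
    """Inter-nucleotide boundary support from half-fragment termini.

    Boundary key j means the junction between sequence indices j-1 and j.
    ``from_five_ends`` counts 5'-half 3'-termini at that junction;
    ``from_three_starts`` counts 3'-half 5'-termini.
    """

    ref_id: str
    from_five_ends: Counter = field(default_factory=Counter)
    from_three_starts: Counter = field(default_factory=Counter)

    def concordant_boundaries(self) -> list[int]:
        return sorted(set(self.from_five_ends) & set(self.from_three_starts))

    def modal_boundary(self) -> int | None:
        combined = self.from_five_ends + self.from_three_starts
        if not combined:
            return None
        return max(sorted(combined), key=lambda j: combined[j])


def infer_cleavage_sites(calls: list[FragmentCall], trna: TRNARecord) -> CleavageProfile:
    """Aggregate anticodon-loop cleavage evidence for one tRNA record.

    A 5'-half ending at index i supports the junction (i, i+1), key i+1; a
    3'-half starting at index j supports the junction (j-1, j), key j.
    """
    profile = CleavageProfile(ref_id=trna.ref_id)
    for c in calls:
        if c.ref_id != trna.ref_id:
            continue
        if c.fragment_class is FragmentClass.FIVE_HALF:
            profile.from_five_ends[c.end] += 1  # end is half-open: last index + 1
        elif c.fragment_class is FragmentClass.THREE_HALF:
            profile.from_three_starts[c.start] += 1
    return profile


@dataclass
class AlignmentProfile:
    ref_id: str
    starts: np.ndarray
    ends: np.ndarray
    coverage: np.ndarray
    top_intervals: list[tuple[tuple[int, int], int]]


def alignment_profile(
    assignments, ref_id: str, ref_length: int, n_top: int = 5
) -> AlignmentProfile:
    """Per-position start/end/coverage vectors and the most frequent intervals."""
    starts = np.zeros(ref_length, dtype=np.int64)
    ends = np.zeros(ref_length, dtype=np.int64)
    delta = np.zeros(ref_length + 1, dtype=np.int64)
    intervals: Counter = Counter()
    for aln in assignments:
        if aln.ref_id != ref_id:
            continue
        starts[aln.start] += 1
        ends[aln.end - 1] += 1
        delta[aln.start] += 1
        delta[aln.end] -= 1
        intervals[(aln.start, aln.end)] += 1
    coverage = np.cumsum(delta[:-1])
    top = sorted(intervals.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
    return AlignmentProfile(ref_id, starts, ends, coverage, top)


def length_distribution(
    lengths, min_len: int = 20, max_len: int = 45
) -> pd.Series:
    """Histogram of fragment lengths over the selection window."""
    hist = pd.Series(0, index=range(min_len, max_len + 1), dtype=int)
    for length in lengths:
        if min_len <= length <= max_len:
            hist[length] += 1
    return hist


def write_composition(path, matrix: CompositionMatrix) -> None:
    df = matrix.fractions.copy()
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def write_cleavage_profile(path, profiles: list[CleavageProfile]) -> None:
    rows = []
    for p in profiles:
        for j in sorted(set(p.from_five_ends) | set(p.from_three_starts)):
            rows.append(
                {
                    "ref_id": p.ref_id,
                    "boundary_after_1based": j,  # junction between 1-based j and j+1
                    "from_five_half_ends": p.from_five_ends.get(j, 0),
                    "from_three_half_starts": p.from_three_starts.get(j, 0),
                    "concordant": int(j in p.from_five_ends and j in p.from_three_starts),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "ref_id",
            "boundary_after_1based",
            "from_five_half_ends",
            "from_three_half_starts",
            "concordant",
        ],
    ).to_csv(path, sep="\t", index=False)
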