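"""FASTQ -> per-condition variant count table.

Pipeline per read pair: mean-Phred quality filter, barcode demultiplexing
against the condition scheme, anchor-based extraction of the randomized
window from either mate (with cross-mate agreement check), exact-sequence
counting.  Counting is exact because the window is only 5-6 nt and per-
variant depth is high; no error correction or clustering is attempted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .designs import (
    CONDITIONS,
    BarcodeScheme,
    LibraryDesign,
    dna_to_rna,
    reverse_complement,
)

TALLY_KEYS = ("fail_quality", "no_barcode", "no_anchor", "ambiguous")


class ReadPair(NamedTuple):
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class VariantCountTable:
    """Per-condition read counts for every observed variant window."""

    design_id: str
    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: {} for c in CONDITIONS}
    )
    tallies: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in TALLY_KEYS}
    )
    reads_in: int = 0

    @property
    def totals(self) -> dict[str, int]:
        return {c: sum(v.values()) for c, v in self.counts.items()}

    def accounting_ok(self) -> bool:
        """reads_in == counted reads + every discard tally."""
        return self.reads_in == sum(self.totals.values()) + sum(self.tallies.values())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (condition, variant, count)."""
        rows = [
            (cond, variant, n)
            for cond, cv in self.counts.items()
            for variant, n in sorted(cv.items())
        ]
        return pd.DataFrame(rows, columns=["condition", "variant", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design_id: str = "") -> "VariantCountTable":
        table = cls(design_id=design_id)
        for cond, variant, n in frame[["condition", "variant", "count"]].itertuples(
            index=False
        ):
            table.counts.setdefault(cond, {})[variant] = int(n)
        table.reads_in = sum(table.totals.values())
        return table

    @classmethod
    def from_tsv(cls, path, design_id: str = "") -> "VariantCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), design_id=design_id)


def mean_phred(qual: str) -> float:
    """Mean Phred score of a Sanger-encoded (offset 33) quality string."""
    if not qual:
        raise ValueError("empty quality string")
    raw = qual.encode("ascii")
    if min(raw) < 33:
        raise ValueError("malformed quality string")
    return (sum(raw) - 33 * len(raw)) / len(raw)


def quality_filter(pair: ReadPair, min_mean_q: float = 20.0) -> bool:
    """Keep the pair iff the mean Phred of *each* mate is >= min_mean_q."""
    return (
        mean_phred(pair.qual1) >= min_mean_q and mean_phred(pair.qual2) >= min_mean_q
    )


def _matches_prefix(read: str, barcode: str, max_mismatch: int) -> bool:
    # barcodes sit on the sequencing primers, so they are anchored to the
    # read start; allow a start offset of up to 2 bases
    if read.startswith(barcode):
        return True
    blen = len(barcode)
    for off in range(0, 3):
        window = read[off : off + blen]
        if len(window) < blen:
            break
        mm = 0
        for a, b in zip(window, barcode):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return True
    return False


def demultiplex(
    pair: ReadPair, scheme: BarcodeScheme, max_mismatch: int = 1
) -> str | None:
    """Condition whose forward barcode matches the R1 prefix and reverse
    barcode matches the R2 prefix, or None (no match, or more than one)."""
    hits = [
        cond
        for cond in scheme.conditions
        if _matches_prefix(pair.seq1, scheme.forward(cond), max_mismatch)
        and _matches_prefix(pair.seq2, scheme.reverse(cond), max_mismatch)
    ]
    return hits[0] if len(hits) == 1 else None


def _find_approx(hay: str, needle: str, max_mismatch: int) -> int:
    """Leftmost start of ``needle`` in ``hay`` allowing mismatches (-1 if absent)."""
    pos = hay.find(needle)
    if pos >= 0 or max_mismatch == 0:
        return pos
    nlen = len(needle)
    for start in range(0, len(hay) - nlen + 1):
        mm = 0
        for a, b in zip(hay[start : start + nlen], needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return start
    return -1


def _window_from_mate(seq: str, design: LibraryDesign, max_mismatch: int) -> str | None:
    up, down, k = design.upstream_anchor, design.downstream_anchor, design.k
    pos = _find_approx(seq, up, max_mismatch)
    if pos < 0:
        return None
    start = pos + len(up)
    window = seq[start : start + k]
    if len(window) < k:
        return None
    tail = seq[start + k : start + k + len(down)]
    if len(tail) < len(down):
        return None
    mm = sum(a != b for a, b in zip(tail, down))
    if mm > max_mismatch:
        return None
    if any(b not in "ACGT" for b in window):
        return None
    return window


def extract_variant_detail(
    pair: ReadPair, design: LibraryDesign, max_anchor_mismatch: int = 1
) -> tuple[str | None, str]:
    """(variant, status) where status is 'ok', 'no_anchor' or 'ambiguous'.

    The window is searched in R1 and in the reverse complement of R2; if
    both mates cover it and disagree at any base the pair is discarded as
    ambiguous (conservative rule, no arbitration by quality).
    """
    w1 = _window_from_mate(pair.seq1, design, max_anchor_mismatch)
    w2 = _window_from_mate(reverse_complement(pair.seq2), design, max_anchor_mismatch)
    if w1 is not None and w2 is not None:
        if w1 != w2:
            return None, "ambiguous"
        return dna_to_rna(w1), "ok"
    if w1 is not None:
        return dna_to_rna(w1), "ok"
    if w2 is not None:
        return dna_to_rna(w2), "ok"
    return None, "no_anchor"


def extract_variant(
    pair: ReadPair, design: LibraryDesign, max_anchor_mismatch: int = 1
) -> str | None:
    """The variant window (RNA) carried by a read pair, or None."""
    variant, status = extract_variant_detail(pair, design, max_anchor_mismatch)
    return variant if status == "ok" else None


def count_variants(
    pairs: Iterable[ReadPair | tuple],
    design: LibraryDesign,
    scheme: BarcodeScheme,
    min_mean_q: float = 20.0,
    barcode_mismatch: int = 1,
    anchor_mismatch: int = 1,
    swap_mates: bool = False,
) -> VariantCountTable:
    """Run quality filter -> demultiplex -> extraction over a read stream.

    Accepts ReadPair instances or plain (id, seq1, qual1, seq2, qual2)
    tuples.  ``swap_mates`` flips the forward/reverse barcode orientation
    for data where the reverse primer was read as R1.
    """
    table = VariantCountTable(design_id=design.region_id)
    counts = table.counts
    tallies = table.tallies
    for rec in pairs:
        rid, s1, q1, s2, q2 = rec
        if swap_mates:
            s1, q1, s2, q2 = s2, q2, s1, q1
        pair = ReadPair(rid, s1, q1, s2, q2)
        table.reads_in += 1
        if not quality_filter(pair, min_mean_q):
            tallies["fail_quality"] += 1
            continue
        condition = demultiplex(pair, scheme, barcode_mismatch)
        if condition is None:
            tallies["no_barcode"] += 1
            continue
        variant, status = extract_variant_detail(pair, design, anchor_mismatch)
        if status != "ok":
            tallies[status] += 1
            continue
        bucket = counts[condition]
        bucket[variant] = bucket.get(variant, 0) + 1
    return table


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two (optionally gzipped) FASTQs."""
    with _open_maybe_gzip(path1) as f1, _open_maybe_gzip(path2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield ReadPair(t1.split()[0], s1, q1, s2, q2)


def count_fastq(
    fastq_pairs: Iterable[tuple],
    design: LibraryDesign,
    scheme: BarcodeScheme,
    **params,
) -> VariantCountTable:
    """Count variants across one or more (R1 path, R2 path) FASTQ pairs."""

    def stream():
        for p1, p2 in fastq_pairs:
            yield from iter_fastq_pairs(p1, p2)

    return count_variants(stream(), design, scheme, **params)
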