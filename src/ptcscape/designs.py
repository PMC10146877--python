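"""Library designs, barcode schemes and coordinate conventions.

A saturation library fully randomizes a short contiguous window (5-6
positions) of the 23S rRNA on a sequencing amplicon.  Everything downstream
-- simulation, counting, fitness, entropy, epistasis -- is expressed in the
coordinates defined here: 1-based E. coli 23S numbering, RNA bases (A/C/G/U)
for variants and wild-type identities, DNA (A/C/G/T) for reads, barcodes and
anchors.  The single T<->U transliteration happens at the read-extraction
boundary in :mod:`ptcscape.reads`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import yaml

RNA_BASES = ("A", "C", "G", "U")
DNA_BASES = ("A", "C", "G", "T")
CONDITIONS = ("positive", "negative", "unselected")

# The library built by Gibson assembly is referred to under two region labels
# in the source material; both point to the same 2583-2588 design here.
REGION_ALIASES = {"2053-2058": "2583-2588"}


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """A mutagenized window of the 23S rRNA on its sequencing amplicon.

    Parameters
    ----------
    region_id:
        Short label with inclusive endpoints, e.g. ``"2058-2062"``.
    positions:
        Ordered, contiguous, 1-based 23S rRNA positions of the window.
    wt_bases:
        Wild-type RNA base per position (A/C/G/U), same order as positions.
    upstream_anchor, downstream_anchor:
        DNA sequences flanking the randomized window on the amplicon; used
        to locate the window inside a read.
    wt_source:
        Optional per-position provenance flag for the wild-type identity.
    """

    region_id: str
    positions: tuple[int, ...]
    wt_bases: str
    upstream_anchor: str
    downstream_anchor: str
    wt_source: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.wt_bases):
            raise ValueError("positions and wt_bases lengths differ")
        diffs = [b - a for a, b in zip(self.positions, self.positions[1:])]
        if any(d != 1 for d in diffs):
            raise ValueError("positions must be strictly increasing and contiguous")
        if not set(self.wt_bases) <= set(RNA_BASES):
            raise ValueError(f"wt_bases must be RNA (A/C/G/U): {self.wt_bases!r}")
        for name in ("upstream_anchor", "downstream_anchor"):
            anchor = getattr(self, name)
            if not anchor or not set(anchor) <= set(DNA_BASES):
                raise ValueError(f"{name} must be nonempty unambiguous DNA")
        object.__setattr__(self, "positions", tuple(self.positions))
        if self.wt_source:
            if len(self.wt_source) != len(self.positions):
                raise ValueError("wt_source length mismatch")
            object.__setattr__(self, "wt_source", tuple(self.wt_source))

    @property
    def k(self) -> int:
        """Number of randomized positions."""
        return len(self.positions)

    @property
    def diversity(self) -> int:
        """Theoretical library diversity, 4**k."""
        return 4 ** self.k

    @property
    def wt(self) -> str:
        """The wild-type window as an RNA string."""
        return self.wt_bases

    def variants(self) -> Iterator[str]:
        """Enumerate all 4**k variant windows (RNA) in lexicographic order."""
        for combo in itertools.product(RNA_BASES, repeat=self.k):
            yield "".join(combo)

    def position_index(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} not in design {self.region_id}")

    def hamming_to_wt(self, variant: str) -> int:
        """Number of positions at which ``variant`` differs from wild type."""
        return hamming_to_wt(variant, self)


def hamming_to_wt(variant: str, design: LibraryDesign) -> int:
    """Hamming distance between a variant window and the design's WT window."""
    if len(variant) != design.k:
        raise ValueError(
            f"variant length {len(variant)} != design window length {design.k}"
        )
    return sum(a != b for a, b in zip(variant, design.wt_bases))


@dataclass(frozen=True)
class BarcodeScheme:
    """Per-condition forward (R1) and reverse (R2) demultiplexing barcodes."""

    barcodes: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        flat = []
        for cond, pair in self.barcodes.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            fwd, rev = pair
            for bc in (fwd, rev):
                if not set(bc) <= set(DNA_BASES):
                    raise ValueError(f"barcode {bc!r} contains ambiguity codes")
                flat.append(bc)
        if len(set(flat)) != len(flat):
            raise ValueError("barcodes must be distinct")
        for a in flat:
            for b in flat:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a!r} is a prefix of {b!r}")
        object.__setattr__(self, "barcodes", dict(self.barcodes))

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.barcodes)

    def forward(self, condition: str) -> str:
        return self.barcodes[condition][0]

    def reverse(self, condition: str) -> str:
        return self.barcodes[condition][1]


def _load_bundled() -> dict:
    text = resources.files("ptcscape.data").joinpath("designs.yaml").read_text()
    return yaml.safe_load(text)


def _design_from_dict(entry: Mapping) -> LibraryDesign:
    return LibraryDesign(
        region_id=str(entry["region_id"]),
        positions=tuple(int(p) for p in entry["positions"]),
        wt_bases=str(entry["wt_bases"]),
        upstream_anchor=str(entry["upstream_anchor"]),
        downstream_anchor=str(entry["downstream_anchor"]),
        wt_source=tuple(entry.get("wt_source", ())),
    )


def builtin_designs() -> list[LibraryDesign]:
    """The six built-in PTC / exit-tunnel saturation-library designs.

    Five 5-position windows (diversity 1024) and the 6-position 2583-2588
    window (diversity 4096).  Wild-type identities carry a per-position
    provenance flag; see the bundled ``designs.yaml``.
    """
    return [_design_from_dict(d) for d in _load_bundled()["designs"]]


def get_design(region_id: str) -> LibraryDesign:
    """Look up a built-in design by region label (aliases resolved)."""
    region_id = REGION_ALIASES.get(region_id, region_id)
    for d in builtin_designs():
        if d.region_id == region_id:
            return d
    raise KeyError(f"no built-in design {region_id!r}")


def builtin_barcodes() -> BarcodeScheme:
    """The published condition barcodes (forward, reverse) per condition."""
    raw = _load_bundled()["barcode_scheme"]
    return BarcodeScheme(
        {cond: (entry["forward"], entry["reverse"]) for cond, entry in raw.items()}
    )


def load_config(path) -> tuple[list[LibraryDesign], BarcodeScheme]:
    """Read designs + barcode scheme from a user YAML config (same schema
    as the bundled ``designs.yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    designs = [_design_from_dict(d) for d in raw["designs"]]
    scheme = BarcodeScheme(
        {
            cond: (entry["forward"], entry["reverse"])
            for cond, entry in raw["barcode_scheme"].items()
        }
    )
    return designs, scheme


def save_config(path, designs: list[LibraryDesign], scheme: BarcodeScheme) -> None:
    """Write designs + barcode scheme to YAML (round-trips with load_config)."""
    raw = {
        "barcode_scheme": {
            cond: {"forward": fwd, "reverse": rev}
            for cond, (fwd, rev) in scheme.barcodes.items()
        },
        "designs": [
            {
                "region_id": d.region_id,
                "positions": list(d.positions),
                "wt_bases": d.wt_bases,
                "wt_source": list(d.wt_source),
                "upstream_anchor": d.upstream_anchor,
                "downstream_anchor": d.downstream_anchor,
            }
            for d in designs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
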