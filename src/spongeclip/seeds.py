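"""miRNA seed motifs, seed families, and typed seed-site scanning.

Seed motifs are stored and reported in miRNA 5'→3' orientation (positions
2–8 for the 7-nt motif, 1–8 for the 8-nt motif, U→T) and matched on the
3'UTR *sense* strand via reverse complement.  Site-type nomenclature is the
canonical one:

=========  ==============================================================
6mer       match to miRNA positions 2–7
7mer-m8    match to positions 2–8
7mer-A1    match to positions 2–7 plus an A opposite miRNA position 1
8mer       match to positions 2–8 plus the A1 adenosine
=========  ==============================================================

6mer sites are excluded from all downstream seed-match analyses by default.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass

from .annotation import revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
# longest-match precedence at one anchor locus
SITE_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 2, "6mer": 1}

_RNA = set("ACGU")
_DNA = set("ACGT")


class SeedError(ValueError):
    pass


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence with its seed-family assignment."""

    name: str
    mature_seq: str
    family_id: str

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper().replace("T", "U")
        object.__setattr__(self, "mature_seq", seq)
        if len(seq) < 9:
            raise SeedError(f"{self.name}: mature sequence shorter than 9 nt")
        if not set(seq) <= _RNA:
            raise SeedError(f"{self.name}: mature sequence has non-ACGU characters")


@dataclass(frozen=True)
class SeedFamily:
    """A seed family: shared 7-nt (pos 2–8) and 8-nt (pos 1–8) DNA motifs."""

    family_id: str
    motif7: str
    motif8: str
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif7", self.motif7.upper())
        object.__setattr__(self, "motif8", self.motif8.upper())
        if len(self.motif7) != 7:
            raise SeedError(f"{self.family_id}: motif7 must be 7 nt")
        if len(self.motif8) != 8:
            raise SeedError(f"{self.family_id}: motif8 must be 8 nt")
        for m in (self.motif7, self.motif8):
            if not set(m) <= _DNA:
                raise SeedError(
                    f"{self.family_id}: motif {m!r} has characters outside ACGT"
                )


@dataclass(frozen=True)
class SeedMatch:
    """A typed seed site located on a 3'UTR (transcript orientation).

    ``utr_offset`` is the 0-based start of the site pattern within the UTR;
    ``length`` is the pattern length (6, 7 or 8).
    """

    gene_id: str
    utr_offset: int
    length: int
    site_type: str
    family_id: str

    @property
    def utr_end(self) -> int:
        return self.utr_offset + self.length


def derive_seed(mature_seq: str, first: int = 2, last: int = 8) -> str:
    """DNA seed motif from a mature miRNA sequence.

    ``first``/``last`` are 1-based inclusive miRNA positions; U is replaced
    by T and the motif keeps the miRNA 5'→3' orientation.
    """
    seq = mature_seq.upper().replace("T", "U")
    if first < 1 or last > len(seq) or first > last:
        raise SeedError(
            f"positions {first}-{last} out of bounds for sequence of length {len(seq)}"
        )
    return seq[first - 1 : last].replace("U", "T")


def family_from_mirnas(family_id: str, mirnas: list[MiRNA]) -> SeedFamily:
    """Build a SeedFamily from member miRNAs sharing one seed sequence."""
    seeds7 = {derive_seed(m.mature_seq, 2, 8) for m in mirnas}
    seeds8 = {derive_seed(m.mature_seq, 1, 8) for m in mirnas}
    if len(seeds7) != 1:
        raise SeedError(f"{family_id}: member miRNAs do not share one seed")
    return SeedFamily(
        family_id, seeds7.pop(), seeds8.pop(), tuple(m.name for m in mirnas)
    )


def site_pattern(family: SeedFamily, site_type: str) -> str:
    """Target-site pattern to search on the 3'UTR sense strand.

    The 6mer core is the reverse complement of miRNA positions 2–7
    (``motif7[:6]``); the m8 pairing base extends it 5' and the A1 adenosine
    extends it 3' (the A1 position is an A on the target regardless of the
    miRNA's position-1 base).
    """
    core6 = revcomp(family.motif7[:6])
    if site_type == "6mer":
        return core6
    if site_type == "7mer-m8":
        return revcomp(family.motif7)
    if site_type == "7mer-A1":
        return core6 + "A"
    if site_type == "8mer":
        return revcomp(family.motif7) + "A"
    raise SeedError(f"unknown site type {site_type!r}")


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_utr(
    utr_seq: str,
    families: list[SeedFamily],
    gene_id: str = "",
    include_6mer: bool = False,
) -> list[SeedMatch]:
    """Locate all typed seed sites of the given families in a 3'UTR.

    At one anchor locus the longest site type wins (8mer > 7mer-m8 /
    7mer-A1 > 6mer); overlapping sites of *different* families are all
    reported independently.  6mers are omitted unless ``include_6mer``.
    """
    seq = utr_seq.upper().replace("U", "T")
    matches: list[SeedMatch] = []
    for fam in families:
        pat8 = site_pattern(fam, "8mer")
        pat7m8 = site_pattern(fam, "7mer-m8")
        pat7a1 = site_pattern(fam, "7mer-A1")
        core6 = site_pattern(fam, "6mer")
        m8_base = pat7m8[0]

        eight = _find_all(seq, pat8)
        m8 = [s for s in _find_all(seq, pat7m8) if seq[s + 7 : s + 8] != "A"]
        a1 = [
            s
            for s in _find_all(seq, pat7a1)
            if not (s >= 1 and seq[s - 1] == m8_base)
        ]
        for s in eight:
            matches.append(SeedMatch(gene_id, s, 8, "8mer", fam.family_id))
        for s in m8:
            matches.append(SeedMatch(gene_id, s, 7, "7mer-m8", fam.family_id))
        for s in a1:
            matches.append(SeedMatch(gene_id, s, 7, "7mer-A1", fam.family_id))
        if include_6mer:
            six = [
                s
                for s in _find_all(seq, core6)
                if not (s >= 1 and seq[s - 1] == m8_base)
                and seq[s + 6 : s + 7] != "A"
            ]
            for s in six:
                matches.append(SeedMatch(gene_id, s, 6, "6mer", fam.family_id))
    matches.sort(key=lambda m: (m.utr_offset, m.family_id, m.site_type))
    return matches


# ---------------------------------------------------------------------------
# Family table I/O


def load_family_table(path: str | os.PathLike) -> list[SeedFamily]:
    """Read a seed-family table (TSV: family_id, motif7, motif8, members).

    Members are semicolon-separated.  Motifs must be DNA (a U anywhere is an
    error); the table is data, not derived, so motif7 is *not* required to
    equal motif8 positions 2–8 (annotated assignments sometimes differ from
    what the canonical mature sequence would give).
    """
    families = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["family_id", "motif7", "motif8", "members"]
        if header[: len(required)] != required:
            raise SeedError(
                f"{path}: expected columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SeedError(f"{path}: line {lineno}: expected 4 fields")
            fam_id, motif7, motif8, members = fields[:4]
            try:
                families.append(
                    SeedFamily(
                        fam_id,
                        motif7,
                        motif8,
                        tuple(m for m in members.split(";") if m),
                    )
                )
            except SeedError as exc:
                raise SeedError(f"{path}: line {lineno}: {exc}") from exc
    return families


def write_family_table(families: list[SeedFamily], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tmotif7\tmotif8\tmembers\n")
        for f in families:
            fh.write(
                f"{f.family_id}\t{f.motif7}\t{f.motif8}\t{';'.join(f.members)}\n"
            )


def default_families() -> list[SeedFamily]:
    """The shipped seed-family table (miR-17-92 cluster families plus miR-9).

    Motif strings follow the published annotation for these families
    (including the miR-18 8mer "AAGTGCAT", which is annotation data rather
    than a derivation from the canonical mature sequence).
    """
    ref = importlib.resources.files("spongeclip") / "data" / "seed_families.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_family_table(path)
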