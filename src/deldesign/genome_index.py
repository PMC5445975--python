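"""Genome PAM scanning and the spacer suffix-count database.

Every 20-nt sequence immediately 5' of an NGG motif (on either strand) is a
potential Cas9 protospacer.  This module finds all of them, and counts, for
each PAM-proximal suffix length k in 8..20 step 2, how many protospacers in
the genome share that suffix.  Those counts power both the genome-uniqueness
filter (count at k=20 == 1) and the similarity profile used for ranking.

Coordinates are 1-based inclusive on the plus strand throughout; conversion
to 0-based offsets happens only at string indexing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3
#: PAM-proximal suffix lengths counted in the database, longest first.
SUFFIX_KS: tuple[int, ...] = (20, 18, 16, 14, 12, 10, 8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class SequenceError(ValueError):
    """Raised for sequences outside the A/C/G/T/N alphabet."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the A/C/G/T/N alphabet.

    Raises :class:`SequenceError` naming the first offending character and
    its 1-based position.
    """
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise SequenceError(
                f"invalid character {ch!r} at position {i + 1}; expected A/C/G/T/N"
            )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """Named chromosomes of uppercase DNA (A/C/G/T/N)."""

    chromosomes: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise SequenceError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise SequenceError(f"chromosome {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise SequenceError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        """Read a multi-record FASTA (wrapped lines, CRLF tolerated).

        Lowercase / soft-masked input is uppercased; masking is ignored.
        """
        chroms: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in chroms:
                raise SequenceError(f"duplicate chromosome name {rec.id!r} in {path}")
            chroms[rec.id] = str(rec.seq).upper()
        if not chroms:
            raise SequenceError(f"no FASTA records found in {path}")
        return cls(chroms)

    def sequence(self, chrom: str) -> str:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r}; known: {sorted(self.chromosomes)}"
            ) from None

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring of a chromosome."""
        seq = self.sequence(chrom)
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"slice {start}-{end} outside {chrom} (valid 1-{len(seq)})"
            )
        return seq[start - 1 : end]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.chromosomes):
            h.update(name.encode())
            h.update(b"\0")
            h.update(self.chromosomes[name].encode())
            h.update(b"\0")
        return h.hexdigest()


@dataclass(frozen=True)
class PamSite:
    """A 20-nt protospacer adjacent to an NGG PAM.

    ``spacer`` is written 5'->3' on the site's own strand; all coordinates
    are 1-based inclusive on the plus strand.
    """

    chrom: str
    strand: str
    pam_start: int
    pam_end: int
    spacer: str
    spacer_start: int
    spacer_end: int
    pam: str

    def __post_init__(self) -> None:
        assert self.strand in "+-"
        assert self.pam_end - self.pam_start == PAM_LEN - 1
        assert self.spacer_end - self.spacer_start == SPACER_LEN - 1
        assert len(self.spacer) == SPACER_LEN

    def suffix(self, k: int) -> str:
        """PAM-proximal k-suffix of the spacer (its 3' end)."""
        return self.spacer[-k:]


def scan_pams(genome: GenomeSequence) -> list[PamSite]:
    """Find every PAM-adjacent full-length protospacer on both strands.

    A site is emitted only when the 20-nt spacer fits entirely on the
    chromosome and neither spacer nor PAM contains N.  Sorted by
    (chrom, pam_start, strand).
    """
    sites: list[PamSite] = []
    skipped_n = 0
    for chrom in genome.chromosomes:
        seq = genome.sequence(chrom)
        n = len(seq)
        # plus strand: spacer[i-20:i] + NGG at i (0-based)
        for i in range(SPACER_LEN, n - 2):
            if seq[i + 1] == "G" and seq[i + 2] == "G":
                spacer = seq[i - SPACER_LEN : i]
                pam = seq[i : i + 3]
                if "N" in spacer or pam[0] == "N":
                    skipped_n += 1
                    continue
                sites.append(
                    PamSite(
                        chrom=chrom,
                        strand="+",
                        pam_start=i + 1,
                        pam_end=i + 3,
                        spacer=spacer,
                        spacer_start=i - SPACER_LEN + 1,
                        spacer_end=i,
                        pam=pam,
                    )
                )
        # minus strand: plus-strand CCN at j, spacer on plus at j+3..j+22
        for j in range(0, n - SPACER_LEN - 2):
            if seq[j] == "C" and seq[j + 1] == "C":
                block = seq[j : j + SPACER_LEN + 3]
                if "N" in block[2:]:  # N allowed only at the PAM's N position
                    skipped_n += 1
                    continue
                sites.append(
                    PamSite(
                        chrom=chrom,
                        strand="-",
                        pam_start=j + 1,
                        pam_end=j + 3,
                        spacer=reverse_complement(block[3:]),
                        spacer_start=j + 4,
                        spacer_end=j + 23,
                        pam=reverse_complement(block[:3]),
                    )
                )
    if skipped_n:
        logger.info("skipped %d candidate sites containing N", skipped_n)
    sites.sort(key=lambda s: (s.chrom, s.pam_start, s.strand))
    return sites


@dataclass
class SgrnaIndex:
    """Genome-wide counts of PAM-adjacent spacers and their suffixes."""

    spacer_counts: Counter = field(default_factory=Counter)
    suffix_counts: dict[int, Counter] = field(
        default_factory=lambda: {k: Counter() for k in SUFFIX_KS}
    )
    genome_checksum: str | None = None

    @property
    def total_sites(self) -> int:
        return sum(self.spacer_counts.values())


def build_index(
    sites: Iterable[PamSite], genome_checksum: str | None = None
) -> SgrnaIndex:
    """Count spacers and PAM-proximal suffixes over a site collection."""
    index = SgrnaIndex(genome_checksum=genome_checksum)
    for site in sites:
        if len(site.spacer) != SPACER_LEN:
            raise SequenceError(
                f"internal inconsistency: spacer of length {len(site.spacer)} at "
                f"{site.chrom}:{site.spacer_start}"
            )
        index.spacer_counts[site.spacer] += 1
        for k in SUFFIX_KS:
            index.suffix_counts[k][site.suffix(k)] += 1
    return index


def index_genome(genome: GenomeSequence) -> SgrnaIndex:
    """Scan and index in one step, stamping the genome checksum."""
    return build_index(scan_pams(genome), genome_checksum=genome.checksum())


@dataclass(frozen=True)
class SimilarityProfile:
    """Occurrence counts of a spacer's PAM-proximal suffixes.

    ``counts[i]`` is the number of PAM-adjacent genomic spacers sharing the
    last ``ks[i]`` nucleotides, for ks = (20, 18, ..., 8).  Counts include
    the queried spacer's own genomic occurrence(s), so a genome-unique
    spacer has count 1 at k=20.  Counts are non-decreasing toward small k.
    """

    counts: tuple[int, ...]
    ks: tuple[int, ...] = SUFFIX_KS

    def __post_init__(self) -> None:
        assert len(self.counts) == len(self.ks)

    def count_at(self, k: int) -> int:
        return self.counts[self.ks.index(k)]

    def as_dict(self) -> dict[str, int]:
        return {f"k{k}": c for k, c in zip(self.ks, self.counts)}


def similarity_profile(index: SgrnaIndex, spacer: str) -> SimilarityProfile:
    """Look up suffix-share counts for a 20-nt spacer at every k tier."""
    if len(spacer) != SPACER_LEN:
        raise SequenceError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    if set(spacer) - set("ACGT"):
        raise SequenceError(f"spacer contains non-ACGT characters: {spacer!r}")
    counts = tuple(index.suffix_counts[k][spacer[-k:]] for k in SUFFIX_KS)
    return SimilarityProfile(counts=counts)


# --- index cache (JSON-lines with genome checksum) ------------------------

class StaleIndexError(RuntimeError):
    """Raised when a cached index does not match the supplied genome."""


def save_index(index: SgrnaIndex, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"kind": "header", "checksum": index.genome_checksum,
                             "ks": list(SUFFIX_KS)}) + "\n")
        fh.write(json.dumps({"kind": "spacers",
                             "counts": dict(index.spacer_counts)}) + "\n")
        for k in SUFFIX_KS:
            fh.write(json.dumps({"kind": "suffix", "k": k,
                                 "counts": dict(index.suffix_counts[k])}) + "\n")


def load_index(path: str | Path, genome: GenomeSequence | None = None) -> SgrnaIndex:
    """Load a cached index; refuse it if stale for the given genome."""
    path = Path(path)
    index = SgrnaIndex()
    with path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["kind"] == "header":
                index.genome_checksum = rec["checksum"]
            elif rec["kind"] == "spacers":
                index.spacer_counts = Counter(rec["counts"])
            elif rec["kind"] == "suffix":
                index.suffix_counts[rec["k"]] = Counter(rec["counts"])
    if genome is not None and index.genome_checksum != genome.checksum():
        raise StaleIndexError(
            f"index cache {path} was built from a different genome "
            f"(checksum mismatch); rebuild with `deldesign index build`"
        )
    return index
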