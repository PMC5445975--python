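"""Resolve user input (gene name or coordinates) into a validated target region."""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .genome_index import GenomeSequence

logger = logging.getLogger(__name__)


class RegionError(ValueError):
    """Invalid chromosome or coordinates."""


class UnknownGeneError(KeyError):
    """Gene identifier not found in the annotation."""


@dataclass(frozen=True)
class TargetRegion:
    """A 1-based inclusive plus-strand interval to be deleted."""

    chrom: str
    start: int
    end: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(
    chrom: str, start: int, end: int, genome: GenomeSequence, label: str = ""
) -> TargetRegion:
    """Validate a coordinate pair against the genome.

    Reversed coordinates are swapped with a logged warning rather than
    rejected.
    """
    if chrom not in genome.chromosomes:
        raise RegionError(
            f"unknown chromosome {chrom!r}; known: {sorted(genome.chromosomes)}"
        )
    if start > end:
        logger.warning("start %d > end %d; swapping", start, end)
        start, end = end, start
    chrom_len = len(genome.sequence(chrom))
    if start < 1 or end > chrom_len:
        raise RegionError(
            f"coordinates {start}-{end} outside chromosome {chrom} "
            f"(valid range 1-{chrom_len})"
        )
    return TargetRegion(chrom, start, end, label or f"{chrom}:{start}-{end}")


def parse_region_string(text: str, genome: GenomeSequence) -> TargetRegion:
    """Parse the canonical ``chrom:start-end`` rendering."""
    m = re.fullmatch(r"(.+):(\d+)-(\d+)", text.strip())
    if not m:
        raise RegionError(f"cannot parse region {text!r}; expected chrom:start-end")
    return parse_region(m.group(1), int(m.group(2)), int(m.group(3)), genome)


@dataclass
class GeneAnnotation:
    """Gene identifier -> (chrom, span start, span end, strand).

    For coding genes the span is the union CDS span across all transcripts;
    for genes without CDS features the gene feature span is used.  Lookup is
    case-insensitive over IDs, primary names, and synonyms.
    """

    records: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    #: case-folded alias -> canonical identifier
    aliases: dict[str, str] = field(default_factory=dict)

    def add(self, ident: str, chrom: str, start: int, end: int, strand: str,
            names: tuple[str, ...] = ()) -> None:
        self.records[ident] = (chrom, start, end, strand)
        for alias in (ident, *names):
            self.aliases[alias.casefold()] = ident

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneAnnotation":
        """Load gene spans from a GFF3 file.

        Attributes searched for identifiers: ID, Name, and comma-split
        synonyms (PomBase dialect).
        """
        db = gffutils.create_db(
            str(path), dbfn=":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        ann = cls()
        for gene in db.features_of_type("gene"):
            cds = list(db.children(gene, featuretype="CDS"))
            if cds:
                start = min(c.start for c in cds)
                end = max(c.end for c in cds)
            else:
                start, end = gene.start, gene.end
            names: list[str] = []
            for key in ("Name", "synonym", "synonyms"):
                for val in gene.attributes.get(key, []):
                    names.extend(s.strip() for s in val.split(",") if s.strip())
            ident = gene.id
            ann.add(ident, gene.seqid, start, end, gene.strand, tuple(names))
        return ann

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Two-column fallback: ``id<TAB>chrom:start-end``."""
        ann = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                ident, span = line.split("\t")
                m = re.fullmatch(r"(.+):(\d+)-(\d+)", span.strip())
                ann.add(ident.strip(), m.group(1), int(m.group(2)),
                        int(m.group(3)), ".")
            except (ValueError, AttributeError):
                raise RegionError(
                    f"{path}:{lineno}: expected 'id<TAB>chrom:start-end', got {line!r}"
                ) from None
        return ann


def resolve_gene(
    name: str, annotation: GeneAnnotation, genome: GenomeSequence
) -> TargetRegion:
    """Map a gene identifier to its deletion target region.

    Unknown names are rejected with the closest matching identifiers.
    """
    ident = annotation.aliases.get(name.casefold())
    if ident is None:
        close = difflib.get_close_matches(
            name.casefold(), list(annotation.aliases), n=5, cutoff=0.4
        )
        suggestions = sorted({annotation.aliases[c] for c in close})
        raise UnknownGeneError(
            f"unknown gene {name!r}"
            + (f"; closest matches: {', '.join(suggestions)}" if suggestions else "")
        )
    chrom, start, end, _strand = annotation.records[ident]
    return parse_region(chrom, start, end, genome, label=name)
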