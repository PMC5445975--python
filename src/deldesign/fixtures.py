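"""Seeded synthetic genomes with known planted sites, and brute-force oracles.

The generator rejection-samples background sequence so that no planted
20-mer recurs anywhere by accident, which keeps the truth table exact.  The
oracle deliberately shares no scanning code with :mod:`.genome_index`: it is
a window-by-window reimplementation used to cross-check it in tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .genome_index import GenomeSequence

_RC = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    # local reverse complement: the oracle must not lean on the main code path
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class PlantedSite:
    """One spacer+PAM block to embed in the synthetic genome.

    ``position`` is the 1-based plus-strand coordinate of the first base of
    the 23-nt block (spacer+PAM for '+', the reverse-complemented block for
    '-').  ``copies`` > 1 plants the identical block at generator-chosen
    extra positions, producing a deliberately non-unique spacer.
    """

    spacer: str
    pam: str = "TGG"
    strand: str = "+"
    position: int = 0  # 0 = let the generator place it
    copies: int = 1

    def block(self) -> str:
        own = self.spacer + self.pam
        return own if self.strand == "+" else _rc(own)


@dataclass
class SyntheticGenomeSpec:
    seed: int
    chrom_lengths: dict[str, int]
    planted: list[tuple[str, PlantedSite]] = field(default_factory=list)
    gc_bias: float = 0.5
    n_runs: list[tuple[str, int, int]] = field(default_factory=list)  # chrom, pos, len

    def plant(self, chrom: str, site: PlantedSite) -> "SyntheticGenomeSpec":
        self.planted.append((chrom, site))
        return self


@dataclass(frozen=True)
class TruthSite:
    """Expected scanner output for a planted block."""

    chrom: str
    strand: str
    pam_start: int
    pam_end: int
    spacer: str
    spacer_start: int
    spacer_end: int


BLOCK = 23  # spacer (20) + PAM (3)


def synth_genome(spec: SyntheticGenomeSpec) -> tuple[GenomeSequence, list[TruthSite]]:
    """Deterministic synthetic genome plus the truth table of planted sites.

    Background is resampled (bounded retries) until it contains no
    accidental copy of any planted spacer on either strand, so each planted
    spacer's genome-wide occurrence count equals its planted copy number.
    """
    rng = random.Random(spec.seed)
    weights = [1 - spec.gc_bias, spec.gc_bias, spec.gc_bias, 1 - spec.gc_bias]

    # resolve placements chromosome by chromosome
    placements: dict[str, list[tuple[int, PlantedSite]]] = {
        c: [] for c in spec.chrom_lengths
    }
    for chrom, site in spec.planted:
        if chrom not in spec.chrom_lengths:
            raise ValueError(f"planted site references unknown chromosome {chrom!r}")
        if len(site.spacer) != 20:
            raise ValueError(f"planted spacer must be 20 nt: {site.spacer!r}")
        n = spec.chrom_lengths[chrom]
        taken = placements[chrom]
        positions: list[int] = []
        if site.position:
            positions.append(site.position)
        while len(positions) < site.copies:
            pos = _find_slot(rng, n, taken, positions)
            positions.append(pos)
        for pos in positions:
            if pos < 1 or pos + BLOCK - 1 > n:
                raise ValueError(
                    f"planted block at {chrom}:{pos} does not fit (1-{n})"
                )
            for other_pos, _ in taken:
                if abs(other_pos - pos) < BLOCK:
                    raise ValueError(
                        f"planted blocks overlap at {chrom}:{pos} and {other_pos}"
                    )
            for prev in positions[: positions.index(pos)]:
                if abs(prev - pos) < BLOCK:
                    raise ValueError(f"planted copies overlap at {chrom}:{pos}")
            taken.append((pos, site))

    spacers = {s.spacer for _, s in spec.planted}
    chroms: dict[str, str] = {}
    truth: list[TruthSite] = []
    for chrom, n in spec.chrom_lengths.items():
        taken = sorted(placements[chrom])
        for _attempt in range(200):
            seq = _draw_background(rng, n, weights)
            for pos, site in taken:
                seq[pos - 1 : pos + BLOCK - 1] = site.block()
            for cname, npos, nlen in spec.n_runs:
                if cname == chrom:
                    seq[npos - 1 : npos - 1 + nlen] = "N" * nlen
            text = "".join(seq)
            if _background_clean(text, spacers, taken):
                chroms[chrom] = text
                break
        else:
            raise ValueError(
                f"could not sample a background for {chrom} free of planted "
                f"20-mers after 200 attempts"
            )
        for pos, site in taken:
            if site.strand == "+":
                truth.append(TruthSite(chrom, "+", pos + 20, pos + 22,
                                       site.spacer, pos, pos + 19))
            else:
                truth.append(TruthSite(chrom, "-", pos, pos + 2,
                                       site.spacer, pos + 3, pos + 22))
    return GenomeSequence(chroms), truth


def _find_slot(rng, n, taken, pending) -> int:
    used = [p for p, _ in taken] + list(pending)
    for _ in range(1000):
        pos = rng.randint(1, n - BLOCK + 1)
        if all(abs(pos - u) >= BLOCK for u in used):
            return pos
    raise ValueError("infeasible packing: no room for planted block")


def _draw_background(rng, n, weights) -> list[str]:
    return rng.choices("ACGT", weights=weights, k=n)


def _background_clean(text, spacers, taken) -> bool:
    for spacer in spacers:
        expected = sum(1 for pos, s in taken if s.spacer == spacer)
        found = _count_occurrences(text, spacer) + _count_occurrences(text, _rc(spacer))
        # a planted block contributes exactly one strand-specific hit
        if found != expected:
            return False
    return True


def _count_occurrences(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


# --- naive oracle ---------------------------------------------------------

@dataclass(frozen=True)
class OracleSite:
    chrom: str
    strand: str
    pam_start: int
    pam_end: int
    spacer: str
    spacer_start: int
    spacer_end: int


def naive_oracle_sites(genome: GenomeSequence) -> list[OracleSite]:
    """Window-by-window PAM scan, independent of the production scanner."""
    sites = []
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        for pos in range(1, n + 1):  # 1-based window starts
            # plus strand: 23-nt window [pos, pos+22], PAM at [pos+20, pos+22]
            if pos + 22 <= n:
                window = seq[pos - 1 : pos + 22]
                if (window[21] == "G" and window[22] == "G"
                        and "N" not in window):
                    sites.append(OracleSite(chrom, "+", pos + 20, pos + 22,
                                            window[:20], pos, pos + 19))
                # minus strand: own-strand window is revcomp of the same slice
                rc = _rc(window)
                if rc[21] == "G" and rc[22] == "G" and "N" not in rc:
                    sites.append(OracleSite(chrom, "-", pos, pos + 2,
                                            rc[:20], pos + 3, pos + 22))
    sites.sort(key=lambda s: (s.chrom, s.pam_start, s.strand))
    return sites


def naive_profile(sites: list[OracleSite], spacer: str) -> tuple[int, ...]:
    """Suffix-share counts by comparing the query against every site."""
    out = []
    for k in (20, 18, 16, 14, 12, 10, 8):
        tail = spacer[-k:]
        out.append(sum(1 for s in sites if s.spacer[-k:] == tail))
    return tuple(out)


def write_fixture_files(outdir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a small FASTA + GFF3 + TSV fixture set for CLI-level tests.

    The genome carries two chromosomes with planted unique sites; the GFF3
    annotates a coding gene (with CDS) and a non-coding gene over regions
    that contain plantable sites.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    def rand_spacer():
        return "".join(rng.choice("ACGT") for _ in range(20))

    spec = SyntheticGenomeSpec(seed=seed, chrom_lengths={"I": 3000, "II": 3000})
    for pos in (1200, 1300, 1400):
        spec.plant("I", PlantedSite(rand_spacer(), "TGG", "+", position=pos))
    for pos in (1250, 1350):
        spec.plant("II", PlantedSite(rand_spacer(), "AGG", "+", position=pos))
    spec.plant("II", PlantedSite(rand_spacer(), "TGG", "-", position=1450))
    genome, truth = synth_genome(spec)

    fasta = outdir / "genome.fa"
    with fasta.open("w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gff = outdir / "annotation.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "I\ttest\tgene\t1100\t1600\t.\t+\t.\tID=SPTEST.01;Name=cdc2\n"
        "I\ttest\tmRNA\t1100\t1600\t.\t+\t.\tID=SPTEST.01.1;Parent=SPTEST.01\n"
        "I\ttest\tCDS\t1150\t1450\t.\t+\t0\tID=SPTEST.01.1:cds;Parent=SPTEST.01.1\n"
        "II\ttest\tgene\t1200\t1500\t.\t-\t.\tID=SPNCRNA.01\n"
    )

    tsv = outdir / "genes.tsv"
    tsv.write_text("cdc2\tI:1150-1450\nSPNCRNA.01\tII:1200-1500\n")
    return {"fasta": fasta, "gff3": gff, "tsv": tsv}
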