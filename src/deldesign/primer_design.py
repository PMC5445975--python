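"""Primer construction for seamless deletion.

Three primer sets are produced:

* sgRNA cloning primers that amplify the whole expression plasmid by
  inverse PCR, carrying the 20-nt spacer at their 5' ends (a ligation
  method and a ligation-free method);
* HR-template primers: the 160-nt homologous-recombination donor is the
  80-nt flanks of the deletion joined together, synthesised from two
  overlapping 100-nt primers;
* checking primers flanking the deletion junction, picked from the joined
  250-nt flanks by a Tm-driven score, with predicted product sizes for the
  deleted and wild-type alleles.

Melting temperatures use SantaLucia (1998) unified nearest-neighbor
thermodynamics at 50 mM monovalent salt and 50 nM total oligo.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .genome_index import GenomeSequence, reverse_complement
from .target_resolution import TargetRegion

logger = logging.getLogger(__name__)

HR_FLANK = 80
HR_PRIMER_LEN = 100
MIN_HR_OVERLAP = 20
CHECK_FLANK = 250


class PrimerDesignError(ValueError):
    """Raised when a primer set cannot be constructed as specified."""


@dataclass(frozen=True)
class Primer:
    """An oligo written 5'->3' with optional Tm and footprint."""

    name: str
    seq: str
    tm_celsius: float | None = None
    # 1-based inclusive interval on the genome or plasmid the 3' part anneals to
    footprint: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.seq or set(self.seq) - set("ACGT"):
            raise PrimerDesignError(f"primer {self.name}: invalid sequence {self.seq!r}")

    def __len__(self) -> int:
        return len(self.seq)


# --- melting temperature --------------------------------------------------

# SantaLucia (1998) unified parameters: dH (kcal/mol), dS (cal/mol/K)
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987  # cal/mol/K


@dataclass(frozen=True)
class TmConditions:
    """Duplex conditions; defaults follow the common primer-picking setup."""

    monovalent_mM: float = 50.0
    oligo_nM: float = 50.0


def melting_temperature(seq: str, conditions: TmConditions = TmConditions()) -> float:
    """Nearest-neighbor duplex Tm in Celsius.

    dH/dS are summed over dinucleotide stacks plus terminal initiation
    terms; entropy is salt-corrected with 0.368*(N-1)*ln[monovalent], and
    the duplex concentration term uses CT/4 (non-self-complementary,
    primer in excess over template is not assumed).
    """
    if len(seq) < 8:
        raise PrimerDesignError(f"sequence too short for Tm ({len(seq)} nt, need >=8)")
    if set(seq) - set("ACGT"):
        raise PrimerDesignError(f"non-ACGT character in {seq!r}")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = _INIT_GC if end in "GC" else _INIT_AT
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        pair = _NN_PARAMS[seq[i : i + 2]]
        dh += pair[0]
        ds += pair[1]
    ds += 0.368 * (len(seq) - 1) * math.log(conditions.monovalent_mM / 1000.0)
    ct = conditions.oligo_nM * 1e-9 / 4.0
    return dh * 1000.0 / (ds + _R * math.log(ct)) - 273.15


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


# --- HR template ----------------------------------------------------------

def build_hr_template(
    genome: GenomeSequence, region: TargetRegion, flank: int = HR_FLANK
) -> str:
    """Join the immediate up- and downstream flanks of the deletion.

    Returns genome[start-flank .. start-1] + genome[end+1 .. end+flank],
    exactly 2*flank nt: the donor sequence the cell recombines over.
    """
    chrom_len = len(genome.sequence(region.chrom))
    up_avail = region.start - 1
    down_avail = chrom_len - region.end
    if up_avail < flank:
        raise PrimerDesignError(
            f"need {flank} nt upstream of {region} but only {up_avail} available"
        )
    if down_avail < flank:
        raise PrimerDesignError(
            f"need {flank} nt downstream of {region} but only {down_avail} available"
        )
    up = genome.slice(region.chrom, region.start - flank, region.start - 1)
    down = genome.slice(region.chrom, region.end + 1, region.end + flank)
    return up + down


def design_hr_primers(
    template: str, primer_len: int = HR_PRIMER_LEN
) -> tuple[Primer, Primer]:
    """Two overlapping primers whose extension synthesises the template.

    HRfw is the first ``primer_len`` nt; HRrv the reverse complement of the
    last ``primer_len`` nt.  They must physically overlap (2*primer_len >
    template length) by at least 20 nt for the PCR to prime; the actual
    overlap is reported in the primer names.
    """
    if len(template) < primer_len:
        raise PrimerDesignError(
            f"template ({len(template)} nt) shorter than primer length {primer_len}"
        )
    overlap = 2 * primer_len - len(template)
    if overlap <= 0:
        raise PrimerDesignError(
            f"primers of {primer_len} nt on a {len(template)} nt template would "
            f"not overlap"
        )
    if overlap < MIN_HR_OVERLAP:
        logger.warning(
            "HR primer overlap is %d nt; at least %d nt is recommended",
            overlap, MIN_HR_OVERLAP,
        )
    fw = Primer(name=f"HRfw (overlap {overlap} nt)", seq=template[:primer_len])
    rv = Primer(
        name=f"HRrv (overlap {overlap} nt)",
        seq=reverse_complement(template[-primer_len:]),
    )
    return fw, rv


def hr_overlap(template_len: int, primer_len: int = HR_PRIMER_LEN) -> int:
    return 2 * primer_len - template_len


# --- sgRNA cloning primers ------------------------------------------------

@dataclass(frozen=True)
class PlasmidConfig:
    """Circular expression plasmid and the spacer insertion point.

    ``insertion_point`` p: the spacer is inserted between position p (last
    base of the leader) and p+1 (first base of the guide scaffold), 1-based
    on the plasmid sequence.  ``anneal_len`` is how much plasmid each
    cloning primer anneals to.
    """

    sequence: str
    insertion_point: int
    anneal_len: int = 20

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise PrimerDesignError("plasmid sequence must be A/C/G/T only")
        if not 1 <= self.insertion_point <= len(self.sequence):
            raise PrimerDesignError(
                f"insertion point {self.insertion_point} outside plasmid "
                f"(1-{len(self.sequence)})"
            )
        if self.anneal_len < 1 or self.anneal_len > len(self.sequence):
            raise PrimerDesignError(
                f"anneal_len {self.anneal_len} outside 1-{len(self.sequence)}"
            )
        if self.anneal_len < 15:
            # too short to prime reliably in a real PCR; allowed for toy
            # constructions but flagged
            logger.warning(
                "anneal_len %d is below the recommended minimum of 15",
                self.anneal_len,
            )

    @classmethod
    def from_file(cls, path: str | Path, insertion_point: int,
                  anneal_len: int = 20) -> "PlasmidConfig":
        """Read the plasmid from FASTA or GenBank (by extension)."""
        path = Path(path)
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
        rec = next(SeqIO.parse(str(path), fmt))
        return cls(str(rec.seq).upper(), insertion_point, anneal_len)

    @classmethod
    def toy_default(cls) -> "PlasmidConfig":
        """A documented placeholder for tests and dry runs.

        Real use requires the actual expression plasmid sequence and its
        insertion point; this 80-nt toy merely exercises the construction.
        """
        leader = "ATGACCATGATTACGCCAAGCTATTTAGGTGACACTATAG"
        scaffold = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTC"
        return cls(leader + scaffold, insertion_point=len(leader), anneal_len=20)

    def _circular(self, start: int, length: int) -> str:
        """1-based circular substring of the plasmid."""
        n = len(self.sequence)
        doubled = self.sequence + self.sequence
        start0 = (start - 1) % n
        return doubled[start0 : start0 + length]

    def scaffold_anneal(self) -> str:
        """Plasmid bases p+1 .. p+anneal_len (wraps the origin)."""
        return self._circular(self.insertion_point + 1, self.anneal_len)

    def leader_anneal_rc(self) -> str:
        """Reverse complement of plasmid bases p-anneal_len+1 .. p."""
        return reverse_complement(
            self._circular(self.insertion_point - self.anneal_len + 1, self.anneal_len)
        )

    def expected_circle(self, spacer: str) -> str:
        """The plasmid with the spacer inserted at the insertion point."""
        p = self.insertion_point
        return self.sequence[:p] + spacer + self.sequence[p:]


CLONING_METHODS = ("ligation", "ligation_free")


def design_cloning_primers(
    spacer: str, plasmid: PlasmidConfig, method: str = "ligation_free"
) -> tuple[Primer, Primer]:
    """Inverse-PCR primers that insert the spacer into the plasmid.

    Both methods put the full spacer on the forward primer's 5' end; the
    ligation-free method additionally puts its reverse complement on the
    reverse primer so the bacteria recircularize the product by homology.
    """
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise PrimerDesignError(f"spacer must be 20 nt of A/C/G/T, got {spacer!r}")
    if method not in CLONING_METHODS:
        raise PrimerDesignError(
            f"unknown cloning method {method!r}; choose from {CLONING_METHODS}"
        )
    doubled = plasmid.sequence + plasmid.sequence
    if spacer in doubled or reverse_complement(spacer) in doubled:
        logger.warning(
            "spacer %s already occurs in the plasmid; mispriming risk", spacer
        )
    fw = Primer(name=f"Pfw_{method}", seq=spacer + plasmid.scaffold_anneal())
    if method == "ligation":
        rv = Primer(name=f"Prv_{method}", seq=plasmid.leader_anneal_rc())
    else:
        rv = Primer(
            name=f"Prv_{method}",
            seq=reverse_complement(spacer) + plasmid.leader_anneal_rc(),
        )
    return fw, rv


def simulate_cloning_assembly(
    fw: Primer, rv: Primer, plasmid: PlasmidConfig, method: str
) -> str:
    """Reassemble the circular product implied by an inverse-PCR primer pair.

    The linear PCR product is the forward primer's 5' tail followed by the
    full plasmid walked from the forward anneal start around to the reverse
    anneal end, followed by the reverse primer's 5' tail (as its reverse
    complement on the top strand).  Circularization is blunt ligation
    (ligation method) or recombination across the duplicated spacer tails
    (ligation-free).  Returns the circle rotated to start at plasmid
    position 1 so it can be compared with :meth:`PlasmidConfig.expected_circle`.
    """
    a = plasmid.anneal_len
    fw_anneal = fw.seq[-a:]
    rv_anneal_top = reverse_complement(rv.seq[-a:])
    doubled = plasmid.sequence + plasmid.sequence
    start = doubled.index(fw_anneal)  # 0-based start of forward anneal
    end = doubled.index(rv_anneal_top, start) + a  # past-end of reverse anneal
    amplified = doubled[start:end]  # top strand between the anneal sites
    fw_tail = fw.seq[:-a]
    rv_tail_top = reverse_complement(rv.seq[:-a]) if len(rv.seq) > a else ""
    linear = fw_tail + amplified + rv_tail_top

    if method == "ligation_free":
        # ends share the spacer tail; merge the duplicated homology
        if not (fw_tail and rv_tail_top.endswith(fw_tail)):
            # homology is the fw 5' tail appearing at both ends
            raise PrimerDesignError("ligation-free product ends share no homology")
        linear = linear[: len(linear) - len(fw_tail)]
    circle = linear
    n = len(plasmid.sequence)
    if len(circle) != n + len(fw_tail):
        raise PrimerDesignError(
            f"assembled circle is {len(circle)} nt; expected {n + len(fw_tail)}"
        )

    # rotate so the circle starts at plasmid position 1: the amplified block
    # begins at plasmid offset `start % n`, preceded by the fw tail
    origin_offset = (len(fw_tail) + (n - start % n) % n) % len(circle)
    doubled_circle = circle + circle
    return doubled_circle[origin_offset : origin_offset + len(circle)]


# --- checking primers -----------------------------------------------------

@dataclass(frozen=True)
class PrimerConstraints:
    """Checking-primer picking parameters (Primer3-style defaults)."""

    min_len: int = 18
    opt_len: int = 20
    max_len: int = 25
    min_tm: float = 57.0
    opt_tm: float = 60.0
    max_tm: float = 63.0
    min_gc: float = 0.20
    max_gc: float = 0.80
    max_pair_tm_diff: float = 3.0


@dataclass(frozen=True)
class CheckingDesign:
    forward: Primer
    reverse: Primer
    junction_sequence: str
    product_size_deleted: int
    product_size_wildtype: int


def _enumerate_side(
    flank_seq: str,
    flank_genomic_start: int,
    constraints: PrimerConstraints,
    reverse: bool,
) -> list[tuple[float, int, int, str, float]]:
    """All constraint-passing primers in one flank.

    Returns (score, genomic_start, genomic_end, primer_seq, tm) tuples;
    ``primer_seq`` is already reverse-complemented for the reverse side.
    """
    out = []
    n = len(flank_seq)
    for length in range(constraints.min_len, constraints.max_len + 1):
        for i in range(0, n - length + 1):
            sub = flank_seq[i : i + length]
            if "N" in sub:
                continue
            gc = gc_fraction(sub)
            if not constraints.min_gc <= gc <= constraints.max_gc:
                continue
            tm = melting_temperature(sub)
            if not constraints.min_tm <= tm <= constraints.max_tm:
                continue
            gstart = flank_genomic_start + i
            gend = gstart + length - 1
            seq = reverse_complement(sub) if reverse else sub
            out.append((abs(tm - constraints.opt_tm), gstart, gend, seq, tm))
    return out


def _tightest_violation(
    flank_seq: str, constraints: PrimerConstraints
) -> str:
    """Name the constraint closest to being satisfiable in a failing flank."""
    best: tuple[float, str] | None = None
    for length in range(constraints.min_len, constraints.max_len + 1):
        for i in range(0, len(flank_seq) - length + 1):
            sub = flank_seq[i : i + length]
            if "N" in sub:
                continue
            gc = gc_fraction(sub)
            if gc < constraints.min_gc:
                v = (constraints.min_gc - gc, f"GC below {constraints.min_gc:.0%}")
            elif gc > constraints.max_gc:
                v = (gc - constraints.max_gc, f"GC above {constraints.max_gc:.0%}")
            else:
                tm = melting_temperature(sub)
                if tm < constraints.min_tm:
                    v = (constraints.min_tm - tm, f"Tm below {constraints.min_tm} C")
                elif tm > constraints.max_tm:
                    v = (tm - constraints.max_tm, f"Tm above {constraints.max_tm} C")
                else:
                    continue
            if best is None or v[0] < best[0]:
                best = v
    return best[1] if best else "no candidate windows (flank too short or all N)"


def design_checking_primers(
    genome: GenomeSequence,
    region: TargetRegion,
    flank: int = CHECK_FLANK,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> CheckingDesign:
    """Pick junction-flanking primers and predict both product sizes.

    The junction template is the up-flank joined to the down-flank (what
    the locus looks like after deletion).  The forward primer is chosen in
    the up-flank, the reverse in the down-flank; the pair minimizing
    |Tm_fw - opt| + |Tm_rv - opt| + |Tm_fw - Tm_rv| wins, subject to the
    pair Tm difference cap.  Ties go to the leftmost forward primer, then
    the rightmost reverse primer (largest diagnostic product).
    """
    chrom_len = len(genome.sequence(region.chrom))
    if region.start - 1 < flank or chrom_len - region.end < flank:
        raise PrimerDesignError(
            f"need {flank} nt on both sides of {region} for checking primers; "
            f"available {region.start - 1} up / {chrom_len - region.end} down"
        )
    up = genome.slice(region.chrom, region.start - flank, region.start - 1)
    down = genome.slice(region.chrom, region.end + 1, region.end + flank)
    junction = up + down

    fw_cands = _enumerate_side(up, region.start - flank, constraints, reverse=False)
    rv_cands = _enumerate_side(down, region.end + 1, constraints, reverse=True)
    if not fw_cands:
        raise PrimerDesignError(
            "no forward checking primer satisfies the constraints in the "
            f"upstream flank; tightest violated constraint: "
            f"{_tightest_violation(up, constraints)}"
        )
    if not rv_cands:
        raise PrimerDesignError(
            "no reverse checking primer satisfies the constraints in the "
            f"downstream flank; tightest violated constraint: "
            f"{_tightest_violation(down, constraints)}"
        )

    best_key = None
    best: tuple | None = None
    for fscore, fstart, fend, fseq, ftm in fw_cands:
        for rscore, rstart, rend, rseq, rtm in rv_cands:
            diff = abs(ftm - rtm)
            if diff > constraints.max_pair_tm_diff:
                continue
            key = (fscore + rscore + diff, fstart, -rend)
            if best_key is None or key < best_key:
                best_key = key
                best = (fstart, fend, fseq, ftm, rstart, rend, rseq, rtm)
    if best is None:
        raise PrimerDesignError(
            "no checking-primer pair within the allowed Tm difference of "
            f"{constraints.max_pair_tm_diff} C"
        )
    fstart, fend, fseq, ftm, rstart, rend, rseq, rtm = best
    product_deleted = (region.start - fstart) + (rend - region.end)
    product_wildtype = rend - fstart + 1
    return CheckingDesign(
        forward=Primer("check_fw", fseq, tm_celsius=round(ftm, 2),
                       footprint=(fstart, fend)),
        reverse=Primer("check_rv", rseq, tm_celsius=round(rtm, 2),
                       footprint=(rstart, rend)),
        junction_sequence=junction,
        product_size_deleted=product_deleted,
        product_size_wildtype=product_wildtype,
    )
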