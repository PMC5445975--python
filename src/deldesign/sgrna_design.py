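"""Enumerate, filter, annotate and rank sgRNA candidates in a target region.

Only genome-unique spacers (suffix count 1 at k=20 against the PAM-adjacent
spacer database) are emitted.  Ranking is ascending lexicographic on the
similarity-count tuple from k=20 down to k=8, so the candidate least similar
to anything else in the genome comes first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .genome_index import (
    PAM_LEN,
    SPACER_LEN,
    GenomeSequence,
    PamSite,
    SgrnaIndex,
    SimilarityProfile,
    scan_pams,
    similarity_profile,
)
from .target_resolution import TargetRegion

logger = logging.getLogger(__name__)

#: suffix length at which seed uniqueness is evaluated
SEED_K = 12
#: number of PAM-proximal spacer bases considered editable
MUTATION_WINDOW_LEN = 10
#: blunt cut falls this many bp 5' of the PAM, between spacer positions 17|18
CUT_OFFSET_FROM_PAM = 3
#: how many top-ranked candidates a report shows by default
DEFAULT_REPORT_COUNT = 2


@dataclass(frozen=True)
class SgrnaCandidate:
    site: PamSite
    profile: SimilarityProfile
    seed_unique: bool
    cut_position: int = 0
    mutation_window: tuple[int, int] = (0, 0)
    rank: int = 0
    seed_k: int = SEED_K

    @property
    def spacer(self) -> str:
        return self.site.spacer


def annotate_cut_and_window(cand: SgrnaCandidate) -> SgrnaCandidate:
    """Fill in the predicted blunt-cut coordinate and the editable window.

    The cut lies between spacer positions 17 and 18 from the spacer's 5'
    end (3 bp upstream of the PAM); the stored coordinate is the plus-strand
    position of the spacer base immediately 5' of the cut on the site's own
    strand.  The mutation window is the 10 PAM-proximal spacer bases.
    """
    site = cand.site
    if site.strand == "+":
        cut = site.pam_start - CUT_OFFSET_FROM_PAM - 1
        window = (site.pam_start - MUTATION_WINDOW_LEN, site.pam_start - 1)
    else:
        cut = site.pam_end + CUT_OFFSET_FROM_PAM + 1
        window = (site.pam_end + 1, site.pam_end + MUTATION_WINDOW_LEN)
    assert site.spacer_start < cut < site.spacer_end
    return replace(cand, cut_position=cut, mutation_window=window)


def enumerate_candidates(
    region: TargetRegion,
    genome: GenomeSequence,
    index: SgrnaIndex,
    containment: bool = True,
) -> list[SgrnaCandidate]:
    """All genome-unique PAM-adjacent spacers targetable within the region.

    With ``containment=True`` (default) both spacer and PAM must lie fully
    inside the region; the relaxed mode only requires the PAM inside (the
    spacer may overhang).  A region too short to hold any site yields an
    empty list with a warning, not an error.
    """
    min_len = SPACER_LEN + PAM_LEN if containment else PAM_LEN
    if region.length < min_len:
        logger.warning(
            "region %s is %d nt, shorter than the %d nt needed for a site; "
            "no candidates possible",
            region, region.length, min_len,
        )
        return []

    # scan a padded window so minus-strand sites at the edges are seen,
    # then filter by the containment mode on genomic coordinates
    chrom_len = len(genome.sequence(region.chrom))
    pad = SPACER_LEN
    w_start = max(1, region.start - pad)
    w_end = min(chrom_len, region.end + pad)
    window = GenomeSequence({region.chrom: genome.slice(region.chrom, w_start, w_end)})
    offset = w_start - 1

    candidates: list[SgrnaCandidate] = []
    for local in scan_pams(window):
        site = PamSite(
            chrom=local.chrom,
            strand=local.strand,
            pam_start=local.pam_start + offset,
            pam_end=local.pam_end + offset,
            spacer=local.spacer,
            spacer_start=local.spacer_start + offset,
            spacer_end=local.spacer_end + offset,
            pam=local.pam,
        )
        lo = min(site.spacer_start, site.pam_start)
        hi = max(site.spacer_end, site.pam_end)
        if containment:
            if lo < region.start or hi > region.end:
                continue
        else:
            if site.pam_start < region.start or site.pam_end > region.end:
                continue
        profile = similarity_profile(index, site.spacer)
        if profile.count_at(SPACER_LEN) != 1:
            continue  # not genome-unique
        cand = SgrnaCandidate(
            site=site,
            profile=profile,
            seed_unique=profile.count_at(SEED_K) == 1,
        )
        candidates.append(annotate_cut_and_window(cand))

    if not candidates:
        logger.warning("no unique sgRNA candidates found in %s", region)
    elif len(candidates) < DEFAULT_REPORT_COUNT:
        logger.warning(
            "only %d unique sgRNA candidate(s) in %s; at least %d are "
            "recommended per deletion",
            len(candidates), region, DEFAULT_REPORT_COUNT,
        )
    return candidates


def rank_candidates(candidates: list[SgrnaCandidate]) -> list[SgrnaCandidate]:
    """Total order: ascending profile tuple (k=20 first), then position.

    Ties break by ascending spacer_start, then '+' before '-'.  The rank
    field is assigned 1..n.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.profile.counts, c.site.spacer_start, c.site.strand),
    )
    return [replace(c, rank=i) for i, c in enumerate(ordered, 1)]


def design_sgrnas(
    region: TargetRegion,
    genome: GenomeSequence,
    index: SgrnaIndex,
    containment: bool = True,
) -> list[SgrnaCandidate]:
    """Enumerate + rank in one call."""
    return rank_candidates(enumerate_candidates(region, genome, index, containment))


def candidate_row(cand: SgrnaCandidate) -> dict:
    """Flat record for the TSV/JSON candidate table."""
    site = cand.site
    row = {
        "rank": cand.rank,
        "chrom": site.chrom,
        "strand": site.strand,
        "spacer": site.spacer,
        "pam": site.pam,
        "spacer_start": site.spacer_start,
        "spacer_end": site.spacer_end,
        "cut_position": cand.cut_position,
        "mutation_window_start": cand.mutation_window[0],
        "mutation_window_end": cand.mutation_window[1],
        "seed_unique": cand.seed_unique,
        "seed_k": cand.seed_k,
    }
    row.update(cand.profile.as_dict())
    return row
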