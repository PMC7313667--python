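"""Matching Y-linked transcripts to their X gametologs.

A gametolog pair is a gene whose X and Y copies stopped recombining and
diverged in place.  The Y copy's closest relative in the female
transcriptome is therefore its X counterpart at high — but not perfect —
identity.  Pairing accepts the best full-length match inside an identity
window (default [90%, 99%)): matches at 100% are alleles of a still
recombining locus, matches far below the window are paralogs.

Copy number gives an orthogonal check: the X copy sits at two doses in
females and one in males (female:male depth ~2:1), the Y copy in males
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import Align

from .coverage import MsyCall
from .subtraction import mean_read_depth, revcomp

__all__ = [
    "GametologPair",
    "find_x_gametolog",
    "check_copy_number",
    "synteny_check",
    "DEFAULT_IDENTITY_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_WINDOW = (0.90, 0.99)  # half-open: [low, high)


@dataclass
class GametologPair:
    """A matched X/Y coding-sequence pair for one gene."""

    gene_id: str
    y_id: str
    x_id: str
    y_cds: str
    x_cds: str
    identity: float  # matches / alignment columns of the best global alignment
    alignment_length: int
    copy_number_verdict: str | None = None  # consistent | inconsistent | indeterminate
    x_location: tuple[str, int, int] | None = None


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # affine: a gap of length L costs 4 + L
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _identity(alignment) -> tuple[float, int]:
    counts = alignment.counts()
    matches = counts.identities
    length = alignment.length
    return (matches / length if length else 0.0), length


def find_x_gametolog(
    y_id: str,
    y_seq: str,
    female_transcriptome: dict[str, str],
    identity_window: tuple[float, float] = DEFAULT_IDENTITY_WINDOW,
) -> GametologPair | None:
    """Best full-length match of a Y transcript in the female transcriptome.

    Both strands are searched.  Returns ``None`` when the best hit falls
    outside the identity window (including exact 100% matches, which are
    flagged as alleles rather than gametologs).  Ties on identity break
    by longer alignment, then lexicographic transcript id.
    """
    if not female_transcriptome:
        return None
    aligner = _aligner()
    best: tuple[float, int, str, str] | None = None  # identity, length, id, seq used
    # sorted iteration + strictly-greater comparison = ties break by
    # identity, then alignment length, then lexicographic transcript id
    for x_id in sorted(female_transcriptome):
        x_seq = female_transcriptome[x_id].upper()
        for query in (y_seq.upper(), revcomp(y_seq.upper())):
            aln = aligner.align(query, x_seq)[0]
            ident, length = _identity(aln)
            if best is None or (ident, length) > (best[0], best[1]):
                best = (ident, length, x_id, x_seq)
    ident, length, x_id, x_seq = best
    lo, hi = identity_window
    if ident >= hi - 1e-12:
        logger.info("%s: best hit %s at %.1f%% identity — allelic, not a gametolog", y_id, x_id, 100 * ident)
        return None
    if ident < lo:
        return None
    return GametologPair(
        gene_id=y_id,
        y_id=y_id,
        x_id=x_id,
        y_cds=y_seq,
        x_cds=x_seq,
        identity=ident,
        alignment_length=length,
    )


def check_copy_number(
    pair: GametologPair,
    male_dna: Iterable[tuple[str, str, str]],
    female_dna: Iterable[tuple[str, str, str]],
    identity: float = 0.99,
    ratio_band: tuple[float, float] = (1.41, 2.83),
    female_y_max: float = 0.0,
    k: int = 25,
) -> GametologPair:
    """Verify the 2:1 female:male dose on X and male-only presence of Y.

    The band default is symmetric around 2 on a log scale (2^0.5 to
    2^1.5).  Zero male depth on the X copy makes the test indeterminate
    rather than failing it.  The verdict is stored on the pair and the
    pair returned.
    """
    targets = {"x": pair.x_cds, "y": pair.y_cds}
    male = mean_read_depth(targets, male_dna, identity=identity, k=k)
    female = mean_read_depth(targets, female_dna, identity=identity, k=k)
    if male["x"] == 0 or (male["y"] == 0 and female["y"] == 0 and female["x"] == 0):
        pair.copy_number_verdict = "indeterminate"
        return pair
    ratio = female["x"] / male["x"]
    lo, hi = ratio_band
    x_ok = lo <= ratio <= hi
    y_ok = male["y"] > 0 and female["y"] <= female_y_max
    pair.copy_number_verdict = "consistent" if (x_ok and y_ok) else "inconsistent"
    return pair


def synteny_check(
    pairs: list[GametologPair],
    annotation: pd.DataFrame,
    msy_call: MsyCall | None = None,
) -> dict:
    """Do the X gametologs cluster on one chromosome, inside the MSY call?

    ``annotation`` maps transcript/gene ids to reference coordinates
    (columns: gene_id, chrom, start, end).  Returns the fraction of
    paired genes on the modal chromosome and, when an MSY call is given,
    the fraction falling inside its interval.
    """
    if not pairs:
        return {"n_pairs": 0}
    ann = annotation.set_index("gene_id")
    located = []
    for p in pairs:
        if p.x_id in ann.index:
            row = ann.loc[p.x_id]
            p.x_location = (str(row["chrom"]), int(row["start"]), int(row["end"]))
            located.append(p)
        else:
            logger.warning("%s: X transcript %s not in annotation", p.gene_id, p.x_id)
    if not located:
        return {"n_pairs": len(pairs), "n_located": 0}
    chroms = pd.Series([p.x_location[0] for p in located])
    modal = chroms.mode().iloc[0]
    modal_frac = float((chroms == modal).mean())
    report = {
        "n_pairs": len(pairs),
        "n_located": len(located),
        "modal_chrom": str(modal),
        "modal_fraction": modal_frac,
    }
    if msy_call is not None:
        inside = [
            p
            for p in located
            if p.x_location[0] == msy_call.chrom
            and p.x_location[1] >= msy_call.start
            and p.x_location[2] <= msy_call.end
        ]
        report["fraction_inside_msy"] = len(inside) / len(located)
        report["all_inside_msy"] = len(inside) == len(located)
    return report
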