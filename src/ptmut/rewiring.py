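"""Kinase-motif rewiring scores for mutations flanking PTM sites.

For each mutation within the compile window of a phosphosite, the
+/-7-residue flank of the site is extracted from the reference sequence
(terminal overhangs padded with 'X', which scores a neutral 0), the
single substitution is applied, and both windows are scored against each
kinase position-specific scoring matrix (PSSM).  The delta score

    delta = score(mutant flank) - score(wild-type flank)

is positive when the mutation is predicted to create the kinase motif
(gain of upstream regulation) and negative when it destroys it (loss).
Higher PSSM score = stronger predicted binding here; matrices exported
from tools with the opposite orientation must be sign-flipped on import.

Because the additive score only reads one character per offset, delta
depends solely on the matrix column at the mutated offset; all other
columns cancel.  No stringency threshold is applied by default — every
(site, mutation, kinase) triple is scored ("minimum stringency"); an
empirical background percentile is available for optional filtering.

A second predictor's delta scores can be imported from a TSV keyed by
(site, mutation, kinase) and compared by sign agreement.
"""

from __future__ import annotations

import bisect
import os
from collections import defaultdict
from typing import Callable, Iterable, Sequence

import pandas as pd

from .model import (
    DeltaScore,
    FlankPair,
    IntersectionRecord,
    MutationType,
    PSSM,
    ProteinRecord,
    Relation,
    SignAgreementReport,
    ValidationError,
)

PAD_CHAR = "X"


def extract_flank(protein: ProteinRecord, position: int, half_width: int = 7) -> str:
    """(2*half_width+1)-mer centered on a 1-based position, 'X'-padded."""
    if not 1 <= position <= len(protein):
        raise ValidationError(
            f"{protein.protein_id}: position {position} outside 1..{len(protein)}"
        )
    chars = []
    for pos in range(position - half_width, position + half_width + 1):
        if 1 <= pos <= len(protein):
            chars.append(protein.sequence[pos - 1])
        else:
            chars.append(PAD_CHAR)
    return "".join(chars)


def build_flank_pairs(
    flank_hits: Iterable[IntersectionRecord],
    proteome: dict[str, ProteinRecord],
    half_width: int = 7,
) -> list[FlankPair]:
    """Wild-type/mutant flank pairs for flank-relation intersection records.

    The mutant flank is the wild-type flank with the substitution applied
    at index ``half_width + offset``.  The compile window (default 5) is
    at most the flank half-width, so every flank hit falls inside the
    scored window.
    """
    pairs: list[FlankPair] = []
    for rec in flank_hits:
        if rec.relation is not Relation.FLANK:
            raise ValidationError(f"expected flank relation, got {rec.relation}")
        if abs(rec.offset) > half_width:
            raise ValidationError(
                f"flank offset {rec.offset} outside scoring window +/-{half_width}"
            )
        protein = proteome[rec.site.protein_id]
        wt_flank = extract_flank(protein, rec.site.position, half_width)
        _, _, wt_res, mut_res = rec.mutation_type
        idx = half_width + rec.offset
        if wt_flank[idx] != wt_res:
            raise ValidationError(
                f"{rec.site.protein_id} pos {rec.mutation_type[1]}: sequence has "
                f"{wt_flank[idx]!r}, mutation record says wild-type {wt_res!r}"
            )
        mut_flank = wt_flank[:idx] + mut_res + wt_flank[idx + 1 :]
        pairs.append(
            FlankPair(
                site=rec.site,
                mutation_type=rec.mutation_type,
                wt_flank=wt_flank,
                mut_flank=mut_flank,
            )
        )
    return pairs


def pssm_score(flank: str, pssm: PSSM) -> float:
    """Additive score: sum over offsets of the weight for the residue seen."""
    if len(flank) != 2 * pssm.half_width + 1:
        raise ValidationError(
            f"flank length {len(flank)} != {2 * pssm.half_width + 1} "
            f"expected by PSSM {pssm.kinase_name}"
        )
    total = 0.0
    for i, ch in enumerate(flank):
        if ch == PAD_CHAR:
            total += pssm.pad_score
            continue
        offset = i - pssm.half_width
        try:
            total += pssm.weights[(offset, ch)]
        except KeyError as exc:
            raise ValidationError(
                f"residue {ch!r} at offset {offset} not in PSSM {pssm.kinase_name}"
            ) from exc
    return total


def delta_score(pair: FlankPair, pssm: PSSM) -> DeltaScore:
    wt = pssm_score(pair.wt_flank, pssm)
    mut = pssm_score(pair.mut_flank, pssm)
    return DeltaScore(
        site_protein=pair.site.protein_id,
        site_position=pair.site.position,
        mutation_type=pair.mutation_type,
        kinase_name=pssm.kinase_name,
        kinase_group=pssm.kinase_group,
        wt_score=wt,
        mut_score=mut,
        delta=mut - wt,
    )


def score_all(
    pairs: Sequence[FlankPair],
    pssms: Sequence[PSSM],
    background: dict[str, Callable[[float], float]] | None = None,
    stringency_percentile: float | None = None,
) -> list[DeltaScore]:
    """Score every (flank pair, PSSM) combination.

    With a stringency percentile set, triples whose wild-type AND mutant
    scores both fall below that background percentile are dropped; by
    default nothing is filtered.
    """
    scores = []
    for pair in pairs:
        for pssm in pssms:
            ds = delta_score(pair, pssm)
            if background and pssm.kinase_name in background:
                pct = background[pssm.kinase_name]
                ds.wt_percentile = pct(ds.wt_score)
                ds.mut_percentile = pct(ds.mut_score)
                if stringency_percentile is not None and (
                    ds.wt_percentile < stringency_percentile
                    and ds.mut_percentile < stringency_percentile
                ):
                    continue
            scores.append(ds)
    return scores


def calibrate_background(
    pssm: PSSM,
    proteome: dict[str, ProteinRecord],
    site_residues: frozenset[str] | set[str] = frozenset("STY"),
) -> Callable[[float], float]:
    """Empirical score -> percentile map over all candidate-site flanks.

    Scores every flank centered on a residue in ``site_residues`` across
    the proteome; the returned callable maps a score to the percentage of
    background flanks scoring at or below it.
    """
    scores: list[float] = []
    for protein in proteome.values():
        for pos in range(1, len(protein) + 1):
            if protein.sequence[pos - 1] in site_residues:
                scores.append(pssm_score(extract_flank(protein, pos, pssm.half_width), pssm))
    if not scores:
        raise ValidationError("no eligible residues in proteome for background")
    scores.sort()
    n = len(scores)

    def percentile(score: float) -> float:
        return 100.0 * bisect.bisect_right(scores, score) / n

    return percentile


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def sign_agreement(
    scores_a: Sequence[DeltaScore], scores_b: Sequence[DeltaScore]
) -> SignAgreementReport:
    """Fraction of shared (site, mutation, kinase) triples agreeing in sign.

    Triples where either predictor reports delta exactly 0 are excluded
    from both numerator and denominator and counted separately, since a
    zero is neither predicted gain nor loss.
    """

    def keyed(scores: Sequence[DeltaScore]) -> dict[tuple, DeltaScore]:
        out: dict[tuple, DeltaScore] = {}
        for s in scores:
            key = (s.site_protein, s.site_position, s.mutation_type, s.kinase_name)
            if key in out:
                raise ValidationError(f"duplicate delta-score key {key}")
            out[key] = s
        return out

    a, b = keyed(scores_a), keyed(scores_b)
    shared = sorted(set(a) & set(b))
    n_matched = n_agree = n_zero = 0
    per_group: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for key in shared:
        sa, sb = _sign(a[key].delta), _sign(b[key].delta)
        if sa == 0 or sb == 0:
            n_zero += 1
            continue
        n_matched += 1
        group = a[key].kinase_group
        per_group[group][0] += 1
        if sa == sb:
            n_agree += 1
            per_group[group][1] += 1
    return SignAgreementReport(
        n_matched=n_matched,
        n_agree=n_agree,
        n_zero_excluded=n_zero,
        fraction_agree=(n_agree / n_matched) if n_matched else None,
        per_group={g: (m, ag) for g, (m, ag) in sorted(per_group.items())},
    )


# ---------------------------------------------------------------------------
# External predictor import / delta-score TSV round-trip

DELTA_COLUMNS = [
    "site_protein", "site_position", "protein_id", "position", "wt_residue",
    "mut_residue", "kinase_name", "kinase_group", "wt_score", "mut_score", "delta",
]


def delta_scores_to_frame(scores: Iterable[DeltaScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "site_protein": s.site_protein,
                "site_position": s.site_position,
                "protein_id": s.mutation_type[0],
                "position": s.mutation_type[1],
                "wt_residue": s.mutation_type[2],
                "mut_residue": s.mutation_type[3],
                "kinase_name": s.kinase_name,
                "kinase_group": s.kinase_group,
                "wt_score": s.wt_score,
                "mut_score": s.mut_score,
                "delta": s.delta,
                "wt_percentile": s.wt_percentile,
                "mut_percentile": s.mut_percentile,
            }
        )
    return pd.DataFrame(rows, columns=DELTA_COLUMNS + ["wt_percentile", "mut_percentile"])


def read_delta_scores(
    path: str | os.PathLike, score_orientation: int = 1
) -> list[DeltaScore]:
    """Import delta scores, e.g. from a second predictor.

    ``score_orientation=-1`` flips signs for predictors where a lower raw
    score means a stronger motif match.
    """
    if score_orientation not in (1, -1):
        raise ValueError("score_orientation must be +1 or -1")
    frame = pd.read_csv(path, sep="\t", comment="#")
    scores = []
    for row in frame.itertuples(index=False):
        mt: MutationType = (
            str(row.protein_id), int(row.position), str(row.wt_residue), str(row.mut_residue)
        )
        scores.append(
            DeltaScore(
                site_protein=str(row.site_protein),
                site_position=int(row.site_position),
                mutation_type=mt,
                kinase_name=str(row.kinase_name),
                kinase_group=str(getattr(row, "kinase_group", "") or ""),
                wt_score=score_orientation * float(row.wt_score),
                mut_score=score_orientation * float(row.mut_score),
                delta=score_orientation * float(row.delta),
            )
        )
    return scores
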