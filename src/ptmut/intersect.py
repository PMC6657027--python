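"""Mapping mutations onto PTM sites and enrichment statistics.

Three disjoint relations are distinguished:

* ``direct_loss`` — the mutation replaces the modified residue itself;
* ``mimic`` — a phosphorylatable residue (S/T/Y) at a phosphosite is
  replaced by aspartate or glutamate, whose negative charge mimics the
  constitutively phosphorylated state; these are position-coincident hits
  reported as mimics rather than plain losses;
* ``flank`` — the mutation lands within a window around the site
  (default +/-5 residues, offset 0 excluded) and may rewire the enzyme
  recognition motif without touching the modified residue.

Enrichment of mutations on PTM sites is assessed per (residue, PTM type)
category: the expected count is the number of mutations observed on that
residue letter anywhere, multiplied by the proportion of such residues in
the proteome that carry a site of the category; significance comes from a
two-tailed Fisher exact test on residue positions (site vs non-site ×
mutated vs unmutated).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Sequence

from scipy import stats

from .model import (
    ACIDIC_RESIDUES,
    EnrichmentResult,
    IntersectionRecord,
    MutationRecord,
    MutationType,
    PTMSite,
    ProteinRecord,
    Relation,
    ValidationError,
)

_TIE_REL_TOL = 1e-12


def _distinct_mutation_types(
    mutations: Iterable[MutationRecord],
) -> dict[MutationType, MutationRecord]:
    """One representative record per distinct mutation type, first wins."""
    out: dict[MutationType, MutationRecord] = {}
    for m in mutations:
        out.setdefault(m.mutation_type, m)
    return out


def _sites_by_protein(sites: Iterable[PTMSite]) -> dict[str, list[PTMSite]]:
    grouped: dict[str, list[PTMSite]] = defaultdict(list)
    for s in sites:
        grouped[s.protein_id].append(s)
    return grouped


def _sort_records(records: list[IntersectionRecord]) -> list[IntersectionRecord]:
    records.sort(
        key=lambda r: (r.site.protein_id, r.site.position, r.offset, r.site.ptm_type, r.mutation_type)
    )
    return records


def _is_mimic(mutation: MutationRecord, site: PTMSite) -> bool:
    return (
        site.ptm_type == "phosphorylation"
        and site.residue in "STY"
        and mutation.mut_residue in ACIDIC_RESIDUES
    )


def find_direct_hits(
    mutations: Iterable[MutationRecord], sites: Iterable[PTMSite]
) -> list[IntersectionRecord]:
    """Position-coincident (mutation type, site) pairs.

    Each pair yields one record: a residue carrying several PTM
    annotations fans out into one record per site.  The relation is
    ``mimic`` when the phosphomimetic rule fires, else ``direct_loss``.
    A wild-type residue disagreeing with the site's residue at the same
    position is a data inconsistency and raises.
    """
    by_protein = _sites_by_protein(sites)
    records: list[IntersectionRecord] = []
    for mt, mutation in _distinct_mutation_types(mutations).items():
        for site in by_protein.get(mutation.protein_id, ()):
            if site.position != mutation.position:
                continue
            if site.residue != mutation.wt_residue:
                raise ValidationError(
                    f"{mutation.protein_id} pos {mutation.position}: mutation wild-type "
                    f"{mutation.wt_residue!r} != site residue {site.residue!r}"
                )
            relation = Relation.MIMIC if _is_mimic(mutation, site) else Relation.DIRECT_LOSS
            records.append(
                IntersectionRecord(
                    mutation_type=mt,
                    site=site,
                    relation=relation,
                    offset=0,
                    source=mutation.source,
                )
            )
    return _sort_records(records)


def flag_mimics(
    mutations: Iterable[MutationRecord], sites: Iterable[PTMSite]
) -> list[IntersectionRecord]:
    """The mimic subset of the position-coincident pairs."""
    return [r for r in find_direct_hits(mutations, sites) if r.relation is Relation.MIMIC]


def find_flank_hits(
    mutations: Iterable[MutationRecord],
    sites: Iterable[PTMSite],
    half_width: int = 5,
) -> list[IntersectionRecord]:
    """Pairs with 1 <= |mutation position - site position| <= half_width.

    Offset 0 is excluded (those are direct hits).  All pairs are emitted:
    a mutation may flank several sites and vice versa.
    """
    if half_width < 1:
        raise ValueError(f"half_width must be >= 1, got {half_width}")
    by_protein = _sites_by_protein(sites)
    records: list[IntersectionRecord] = []
    for mt, mutation in _distinct_mutation_types(mutations).items():
        for site in by_protein.get(mutation.protein_id, ()):
            offset = mutation.position - site.position
            if 1 <= abs(offset) <= half_width:
                records.append(
                    IntersectionRecord(
                        mutation_type=mt,
                        site=site,
                        relation=Relation.FLANK,
                        offset=offset,
                        source=mutation.source,
                    )
                )
    return _sort_records(records)


def acidic_mutation_scan(
    mutations: Iterable[MutationRecord], sites: Iterable[PTMSite] = ()
) -> list[tuple[MutationRecord, bool]]:
    """Mutations to D or E, irrespective of PTM status at the position.

    Returns ``(record, on_ptm_site)`` pairs, the flag marking whether the
    wild-type position is a known PTM site.
    """
    site_positions = {(s.protein_id, s.position) for s in sites}
    return [
        (m, (m.protein_id, m.position) in site_positions)
        for m in mutations
        if m.mut_residue in ACIDIC_RESIDUES
    ]


def fisher_enrichment(contingency: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2x2 table.

    Sums hypergeometric point probabilities that do not exceed the
    observed table's probability (relative tie tolerance 1e-12).
    """
    (a, b), (c, d) = contingency
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in contingency table {contingency}")
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if total == 0:
        raise ValueError("contingency table has zero total")
    dist = stats.hypergeom(total, row1, col1)
    p_obs = dist.pmf(a)
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    threshold = p_obs * (1.0 + _TIE_REL_TOL)
    p = sum(float(dist.pmf(x)) for x in range(lo, hi + 1) if dist.pmf(x) <= threshold)
    return min(p, 1.0)


def expected_ptm_mutations(
    mutations: Sequence[MutationRecord],
    sites: Sequence[PTMSite],
    proteome: dict[str, ProteinRecord],
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Observed vs expected mutated PTM sites per (residue, PTM type) category.

    expected = (#mutations observed on that residue letter anywhere)
               x (site residues of the category / residues of that letter
                  in the proteome);
    observed = mutations landing exactly on sites of the category.

    The Fisher table counts distinct proteome residue positions:
    rows = site vs non-site residues of the letter, columns = carrying at
    least one mutation vs none.  Benjamini-Hochberg adjustment across
    categories is optional and off by default.
    """
    # Proteome-wide residue tallies and per-letter mutated position sets.
    letter_totals: dict[str, int] = defaultdict(int)
    for rec in proteome.values():
        for ch in rec.sequence:
            letter_totals[ch] += 1

    mutated_positions: dict[str, set[tuple[str, int]]] = defaultdict(set)
    mutations_on_letter: dict[str, int] = defaultdict(int)
    for m in mutations:
        mutations_on_letter[m.wt_residue] += 1
        mutated_positions[m.wt_residue].add((m.protein_id, m.position))

    categories: dict[tuple[str, str], set[tuple[str, int]]] = defaultdict(set)
    for s in sites:
        if s.protein_id in proteome:
            categories[(s.residue, s.ptm_type)].add((s.protein_id, s.position))

    results: list[EnrichmentResult] = []
    for (residue, ptm_type), site_positions in sorted(categories.items()):
        total_letter = letter_totals.get(residue, 0)
        if total_letter == 0:
            warnings.warn(
                f"residue {residue!r} absent from proteome; skipping {residue}-{ptm_type}",
                stacklevel=2,
            )
            continue
        n_sites = len(site_positions)
        n_mut_letter = mutations_on_letter.get(residue, 0)
        expected = n_mut_letter * (n_sites / total_letter)
        observed = sum(
            1
            for m in mutations
            if m.wt_residue == residue and (m.protein_id, m.position) in site_positions
        )
        mutated = mutated_positions.get(residue, set())
        site_mutated = len(site_positions & mutated)
        nonsite_mutated = len(mutated - site_positions)
        table = (
            (site_mutated, n_sites - site_mutated),
            (nonsite_mutated, total_letter - n_sites - nonsite_mutated),
        )
        results.append(
            EnrichmentResult(
                category=f"{residue}-{ptm_type}",
                residue=residue,
                ptm_type=ptm_type,
                observed=observed,
                expected=expected,
                contingency=table,
                p_value=fisher_enrichment(table),
            )
        )
    if adjust and results:
        adjusted = stats.false_discovery_control(
            [r.p_value for r in results], method="bh"
        )
        for r, q in zip(results, adjusted):
            r.adjusted_p = float(q)
    return results
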