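"""Entropy-based hotspot mutation scoring and the recurrence filter.

A protein's somatic mutations are tallied into distinct mutation types —
exact (position, wild-type, mutant) triples, so e.g. R248W and R248Q are
distinct.  With n total mutations distributed over k types at frequencies
f_i = n_i / n, the Shannon entropy of the type distribution is

    S  = -sum_i f_i ln(f_i)        (nats)
    S0 = ln(k)                     (entropy of the uniform distribution)
    dS = S0 - S

dS ("hotspot score") is 0 when mutations are spread uniformly over the
observed types and grows as a few recurrent changes dominate, the pattern
characteristic of oncogenic driver mutations.  A protein with a single
mutation type has dS = 0 by the formula; the recurrence filter (mutations
seen in >= 3 distinct tumors by default) is the gate that defines the
final hotspot mutation set, independent of dS.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from scipy import stats

from .model import (
    HotspotMutation,
    MutationProfile,
    MutationRecord,
    MutationType,
    ProteinRecord,
    ValidationError,
)

_FLOAT_NOISE = 1e-12


def tally_mutation_profile(
    mutations: Sequence[MutationRecord], context_label: str | None = None
) -> MutationProfile:
    """Tally one protein's mutation records into a frequency profile.

    Each record is one sample occurrence; duplicates of the same
    (protein, position, wt, mut, sample) are assumed collapsed upstream.
    """
    if not mutations:
        raise ValidationError("cannot profile an empty mutation list")
    protein_ids = {m.protein_id for m in mutations}
    if len(protein_ids) != 1:
        raise ValidationError(f"records span multiple proteins: {sorted(protein_ids)}")
    counts: Counter[MutationType] = Counter(m.mutation_type for m in mutations)
    n = sum(counts.values())
    k = len(counts)
    frequencies = {mt: c / n for mt, c in counts.items()}
    entropy_S = -sum(f * math.log(f) for f in frequencies.values())
    entropy_S0 = math.log(k)
    delta = entropy_S0 - entropy_S
    if abs(delta) < _FLOAT_NOISE:
        delta = 0.0
    return MutationProfile(
        protein_id=protein_ids.pop(),
        n=n,
        k=k,
        type_counts=dict(counts),
        frequencies=frequencies,
        entropy_S=entropy_S,
        entropy_S0=entropy_S0,
        delta_S=delta,
        context_label=context_label,
    )


def hotspot_score(profile: MutationProfile) -> float:
    """dS = ln(k) + sum_i f_i ln(f_i), clamped to 0 within float noise."""
    delta = math.log(profile.k) + sum(
        f * math.log(f) for f in profile.frequencies.values()
    )
    if abs(delta) < _FLOAT_NOISE:
        return 0.0
    return delta


def profile_all(
    mutations: Iterable[MutationRecord], per_context: bool = False
) -> list[MutationProfile]:
    """Group records by protein (and optionally cancer type) and profile each."""
    grouped: dict[tuple, list[MutationRecord]] = defaultdict(list)
    for m in mutations:
        key = (m.protein_id, m.context_label) if per_context else (m.protein_id,)
        grouped[key].append(m)
    profiles = []
    for key in sorted(grouped):
        context = key[1] if per_context else None
        profiles.append(tally_mutation_profile(grouped[key], context_label=context))
    return profiles


def recurrence_filter(
    mutations: Iterable[MutationRecord], min_tumors: int = 3
) -> list[HotspotMutation]:
    """Keep mutation types observed in at least ``min_tumors`` distinct samples.

    Output is sorted by tumor count descending, then lexicographically by
    mutation type, so it is invariant to input record order.
    """
    if min_tumors < 1:
        raise ValueError(f"min_tumors must be >= 1, got {min_tumors}")
    samples: dict[MutationType, set[str]] = defaultdict(set)
    context_samples: dict[MutationType, dict[str, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for m in mutations:
        samples[m.mutation_type].add(m.sample_id)
        context_samples[m.mutation_type][m.context_label].add(m.sample_id)
    hotspots = [
        HotspotMutation(
            mutation_type=mt,
            tumor_count=len(sample_set),
            per_context_counts={
                ctx: len(s) for ctx, s in sorted(context_samples[mt].items())
            },
        )
        for mt, sample_set in samples.items()
        if len(sample_set) >= min_tumors
    ]
    hotspots.sort(key=lambda h: (-h.tumor_count, h.mutation_type))
    return hotspots


def mutation_density(profile: MutationProfile, protein: ProteinRecord) -> tuple[float, float]:
    """Length-normalized mutation burden.

    Returns ``(log_density, raw_ratio)`` where ``raw_ratio = n / length``
    and ``log_density = ln(raw_ratio)`` as plotted on a log axis.
    """
    if profile.n == 0:
        raise ValidationError("density undefined for n = 0")
    ratio = profile.n / len(protein)
    return math.log(ratio), ratio


def rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two score samples.

    Thin wrapper over the standard statistic, e.g. for comparing hotspot
    scores of proteins with vs without a recurrent mutation.
    """
    result = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(result.statistic), float(result.pvalue)
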