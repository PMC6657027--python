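"""Shared data model for the mutation/PTM intersection pipeline.

All coordinates are 1-based indices into the protein sequence, matching
the site notation used in the field (e.g. "S33" is serine at position 33).
Isoform-suffixed accessions (e.g. "P04637-2") are distinct proteins.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Sequence alphabet: the 20 standard residues plus 'X' (unknown / padding).
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: Residues that may carry each of the four main PTM types.
PTM_RESIDUE_COMPATIBILITY = {
    "phosphorylation": frozenset("STY"),
    "ubiquitylation": frozenset("K"),
    "acetylation": frozenset("K"),
    "methylation": frozenset("KR"),
}

#: Acidic residues used as phosphomimetic substitutions.
ACIDIC_RESIDUES = frozenset("DE")


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class MutationSource(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"


class Relation(str, enum.Enum):
    """How a mutation relates to a PTM site."""

    DIRECT_LOSS = "direct_loss"
    MIMIC = "mimic"
    FLANK = "flank"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.protein_id}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PTMSite:
    protein_id: str
    position: int
    residue: str
    ptm_type: str
    evidence_refs: int = 0
    is_protein_group: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: site position {self.position} must be >= 1"
            )
        if self.evidence_refs < 0:
            raise ValidationError("evidence_refs must be nonnegative")

    @property
    def category(self) -> str:
        """Compound label such as 'S-phosphorylation' used in enrichment/spectra."""
        return f"{self.residue}-{self.ptm_type}"


def check_ptm_compatibility(site: PTMSite) -> None:
    """Raise unless the residue can carry the stated PTM type.

    Enforced for the four main types only (phospho on S/T/Y, ubiquityl and
    acetyl on K, methyl on K/R); other types pass unchecked.
    """
    compatible = PTM_RESIDUE_COMPATIBILITY.get(site.ptm_type)
    if compatible is not None and site.residue not in compatible:
        raise ValidationError(
            f"{site.protein_id} pos {site.position}: {site.ptm_type} "
            f"incompatible with residue {site.residue!r}"
        )


# (protein_id, position, wt_residue, mut_residue) — the identity of one
# distinct missense change, independent of which sample carries it.
MutationType = tuple[str, int, str, str]


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    position: int
    wt_residue: str
    mut_residue: str
    source: MutationSource
    sample_id: str
    context_label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: mutation position {self.position} must be >= 1"
            )
        if self.wt_residue == self.mut_residue:
            raise ValidationError(
                f"{self.protein_id} pos {self.position}: not missense "
                f"({self.wt_residue}->{self.mut_residue})"
            )

    @property
    def mutation_type(self) -> MutationType:
        return (self.protein_id, self.position, self.wt_residue, self.mut_residue)


@dataclass
class PSSM:
    """Additive position-specific scoring matrix over offsets -w..+w.

    Higher score means stronger predicted motif match.  The padding
    character 'X' (sequence termini) contributes ``pad_score``.
    """

    kinase_name: str
    weights: dict[tuple[int, str], float]
    kinase_group: str = ""
    half_width: int = 7
    pad_score: float = 0.0

    def __post_init__(self) -> None:
        expected = {
            (off, aa)
            for off in range(-self.half_width, self.half_width + 1)
            for aa in AMINO_ACIDS
        }
        have = set(self.weights)
        if have != expected:
            missing = sorted(expected - have)[:3]
            extra = sorted(have - expected)[:3]
            raise ValidationError(
                f"PSSM {self.kinase_name}: weight table incomplete "
                f"(missing e.g. {missing}, unexpected e.g. {extra})"
            )
        for key, w in self.weights.items():
            if not math.isfinite(w):
                raise ValidationError(f"PSSM {self.kinase_name}: non-finite weight at {key}")


@dataclass
class MutationProfile:
    """Per-protein tally of distinct mutation types and the entropy score.

    ``delta_S = ln(k) - S`` measures how far the mutation-type frequency
    distribution departs from uniform; large values indicate that a few
    specific changes dominate (hotspot behaviour).  Scores are in nats.
    """

    protein_id: str
    n: int
    k: int
    type_counts: dict[MutationType, int]
    frequencies: dict[MutationType, float]
    entropy_S: float
    entropy_S0: float
    delta_S: float
    context_label: str | None = None


@dataclass
class HotspotMutation:
    mutation_type: MutationType
    tumor_count: int
    per_context_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class IntersectionRecord:
    mutation_type: MutationType
    site: PTMSite
    relation: Relation
    offset: int  # mutation position - site position
    source: MutationSource

    def __post_init__(self) -> None:
        if self.relation in (Relation.DIRECT_LOSS, Relation.MIMIC):
            if self.offset != 0 or self.mutation_type[1] != self.site.position:
                raise ValidationError("direct/mimic relations require offset 0")
        elif self.offset == 0:
            raise ValidationError("flank relation requires nonzero offset")


@dataclass
class EnrichmentResult:
    category: str
    residue: str
    ptm_type: str
    observed: int
    expected: float
    contingency: tuple[tuple[int, int], tuple[int, int]]
    p_value: float | None = None
    adjusted_p: float | None = None


@dataclass
class FlankPair:
    site: PTMSite
    mutation_type: MutationType
    wt_flank: str
    mut_flank: str

    def __post_init__(self) -> None:
        if len(self.wt_flank) != len(self.mut_flank):
            raise ValidationError("flank length mismatch")
        diff = [i for i, (a, b) in enumerate(zip(self.wt_flank, self.mut_flank)) if a != b]
        if len(diff) != 1:
            raise ValidationError(
                f"wt/mut flanks must differ at exactly one position, got {len(diff)}"
            )
        center = len(self.wt_flank) // 2
        if diff[0] == center:
            raise ValidationError("flanking mutation may not alter the central residue")


@dataclass
class DeltaScore:
    """Wild-type vs mutant PSSM score for one (site, mutation, kinase) triple.

    ``delta = mut_score - wt_score``: positive predicts gain of the kinase
    motif, negative predicts loss.
    """

    site_protein: str
    site_position: int
    mutation_type: MutationType
    kinase_name: str
    kinase_group: str
    wt_score: float
    mut_score: float
    delta: float
    wt_percentile: float | None = None
    mut_percentile: float | None = None


@dataclass
class SignAgreementReport:
    n_matched: int
    n_agree: int
    n_zero_excluded: int
    fraction_agree: float | None
    per_group: dict[str, tuple[int, int]] = field(default_factory=dict)
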