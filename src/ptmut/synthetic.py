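"""Seeded generators for synthetic proteomes, PTM sites, mutation cohorts,
and kinase matrices with planted, manifest-tracked signals.

The generators emulate the statistical structure of real inputs — a
proteome of i.i.d. sequences, PTM sites planted by per-residue Bernoulli
draws at realistic rates, a tumor cohort whose mutations are a Poisson
passenger background plus explicitly planted recurrent hotspots, germline
variants enriched on and around PTM sites with a configurable
phosphomimetic fraction, and PSSMs with planted motif anchors — so every
pipeline stage can be exercised against known ground truth without any
external download.  Every planted signal is recorded exactly once in a
manifest table for recovery checks.

All randomness flows from the single config seed through named
independent substreams, so a fixed config reproduces byte-identical
outputs including the manifest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AMINO_ACIDS,
    MutationRecord,
    MutationSource,
    PSSM,
    PTMSite,
    ProteinRecord,
    ValidationError,
)

# Approximate human proteome amino-acid frequencies (Swiss-Prot statistics,
# rounded); used by the "human" composition preset.
HUMAN_AA_FREQS = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "X": 0.000,
    "Y": 0.027,
}

#: Default per-residue PTM rates, loosely matching the relative abundance
#: of site classes in large PTM repositories (phosphoserine most common).
DEFAULT_PTM_RATES = {
    ("S", "phosphorylation"): 0.08,
    ("T", "phosphorylation"): 0.03,
    ("Y", "phosphorylation"): 0.03,
    ("K", "ubiquitylation"): 0.05,
    ("K", "acetylation"): 0.02,
    ("K", "methylation"): 0.01,
    ("R", "methylation"): 0.01,
}

CANCER_TYPES = ["BLCA", "BRCA", "GBM", "LUAD", "STAD", "UCEC"]
DISEASE_LABELS = ["syndrome_A", "syndrome_B", "cardiomyopathy_X", "dysplasia_Y"]

_FRACTION_PROTEIN_GROUP = 0.065


@dataclass(frozen=True)
class PlantedHotspot:
    protein_index: int
    position: int
    wt_residue: str
    mut_residue: str
    tumor_count: int


@dataclass(frozen=True)
class PlantedFlankEvent:
    """A phosphosite plus one recurrent mutation at a fixed flank offset,
    designed to destroy or create a named kinase motif."""

    protein_index: int
    site_position: int
    offset: int
    wt_residue: str
    mut_residue: str
    kinase_name: str = ""
    tumor_count: int = 3


@dataclass(frozen=True)
class MotifSpec:
    kinase_name: str
    kinase_group: str
    anchors: tuple[tuple[int, str, float], ...]  # (offset, residue, weight)
    noise_sd: float = 0.25


@dataclass
class SimulationConfig:
    seed: int
    n_proteins: int = 120
    length_mean: float = 400.0
    length_sd: float = 100.0
    min_length: int = 50
    #: "uniform", "human", or a residue -> weight mapping
    composition: str | dict[str, float] = "uniform"
    ptm_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PTM_RATES)
    )
    #: expected background (passenger) mutations per residue per cohort
    passenger_rate: float = 0.02
    n_samples: int = 50
    n_germline: int = 300
    #: fraction of germline variants placed on or within +/-5 of a PTM site
    germline_ptm_targeting: float = 0.25
    #: fraction of germline variants drawn as S/T/Y -> D/E on phosphosites
    mimic_fraction: float = 0.05
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    planted_flank_events: list[PlantedFlankEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("passenger_rate", "germline_ptm_targeting", "mimic_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for rate in self.ptm_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"PTM rate {rate} outside [0, 1]")
        for h in self.planted_hotspots:
            if h.tumor_count > self.n_samples:
                raise ValueError(
                    f"planted tumor_count {h.tumor_count} exceeds cohort size {self.n_samples}"
                )


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent substream keyed by (seed, stage name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def generate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if config.length_mean <= 0 or config.min_length < 1:
        raise ValueError("lengths must be positive")
    rng = _stream(config.seed, "proteome")
    if isinstance(config.composition, dict):
        raw = np.array([config.composition.get(aa, 0.0) for aa in AMINO_ACIDS])
        if raw.sum() <= 0 or (raw < 0).any():
            raise ValueError("composition weights must be nonnegative with positive sum")
        probs = raw / raw.sum()
    elif config.composition == "uniform":
        probs = np.full(20, 1 / 20)
    elif config.composition == "human":
        raw = np.array([HUMAN_AA_FREQS[aa] for aa in AMINO_ACIDS])
        probs = raw / raw.sum()
    else:
        raise ValueError(f"unknown composition {config.composition!r}")
    alphabet = np.array(list(AMINO_ACIDS))
    width = len(str(config.n_proteins))
    proteins = []
    for i in range(config.n_proteins):
        length = max(
            config.min_length,
            int(round(rng.normal(config.length_mean, config.length_sd))),
        )
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        proteins.append(ProteinRecord(protein_id=f"SYN{i + 1:0{width}d}", sequence=seq))
    return proteins


def _random_mut(rng: np.random.Generator, wt: str) -> str:
    choices = [aa for aa in AMINO_ACIDS if aa != wt]
    return choices[rng.integers(len(choices))]


def generate_sites_and_mutations(
    config: SimulationConfig, proteome: Sequence[ProteinRecord]
) -> tuple[list[PTMSite], list[MutationRecord], list[MutationRecord], pd.DataFrame]:
    """Sites, somatic cohort, germline variants, and the planted-signal manifest.

    Sites are Bernoulli draws on eligible residues; somatic passengers are
    Poisson-scattered over residues and samples; planted hotspots are
    inserted with their exact distinct-tumor count; planted flank events
    add both the phosphosite and the recurrent flanking mutation; mimic
    variants are S/T/Y -> D/E drawn on planted phosphosites.  The manifest
    records every planted signal exactly once.
    """
    manifest_rows: list[dict] = []

    # --- PTM sites -----------------------------------------------------
    rng = _stream(config.seed, "sites")
    sites: list[PTMSite] = []
    site_keys: set[tuple[str, int, str]] = set()
    for protein in proteome:
        seq = protein.sequence
        for (residue, ptm_type), rate in sorted(config.ptm_rates.items()):
            if rate == 0.0:
                continue
            positions = [i + 1 for i, ch in enumerate(seq) if ch == residue]
            if not positions:
                continue
            hits = rng.random(len(positions)) < rate
            for pos, hit in zip(positions, hits):
                if hit:
                    sites.append(
                        PTMSite(
                            protein_id=protein.protein_id,
                            position=pos,
                            residue=residue,
                            ptm_type=ptm_type,
                            evidence_refs=int(rng.geometric(0.4)),
                            is_protein_group=bool(rng.random() < _FRACTION_PROTEIN_GROUP),
                        )
                    )
                    site_keys.add((protein.protein_id, pos, ptm_type))

    # Planted flank events guarantee their phosphosite exists.
    for ev in config.planted_flank_events:
        protein = proteome[ev.protein_index]
        site_res = protein.residue(ev.site_position)
        if site_res not in "STY":
            raise ValidationError(
                f"planted flank event: {protein.protein_id} pos {ev.site_position} "
                f"is {site_res!r}, not a phosphorylatable residue"
            )
        key = (protein.protein_id, ev.site_position, "phosphorylation")
        if key not in site_keys:
            sites.append(
                PTMSite(
                    protein_id=protein.protein_id,
                    position=ev.site_position,
                    residue=site_res,
                    ptm_type="phosphorylation",
                    evidence_refs=1,
                )
            )
            site_keys.add(key)
    sites.sort(key=lambda s: (s.protein_id, s.position, s.ptm_type))

    # --- somatic cohort ------------------------------------------------
    rng = _stream(config.seed, "somatic")
    somatic: list[MutationRecord] = []
    seen: set[tuple] = set()

    def add_somatic(protein_id, pos, wt, mut, sample, context) -> None:
        key = (protein_id, pos, wt, mut, sample)
        if key in seen:
            return
        seen.add(key)
        somatic.append(
            MutationRecord(
                protein_id=protein_id,
                position=pos,
                wt_residue=wt,
                mut_residue=mut,
                source=MutationSource.SOMATIC,
                sample_id=sample,
                context_label=context,
            )
        )

    sample_ids = [f"tumor{j + 1:03d}" for j in range(config.n_samples)]
    sample_contexts = {
        s: CANCER_TYPES[int(rng.integers(len(CANCER_TYPES)))] for s in sample_ids
    }
    for protein in proteome:
        n_passengers = rng.poisson(config.passenger_rate * len(protein.sequence))
        for _ in range(n_passengers):
            pos = int(rng.integers(1, len(protein.sequence) + 1))
            wt = protein.sequence[pos - 1]
            if wt == "X":
                continue
            sample = sample_ids[int(rng.integers(config.n_samples))]
            add_somatic(
                protein.protein_id, pos, wt, _random_mut(rng, wt), sample, sample_contexts[sample]
            )

    def plant_recurrent(protein, pos, wt, mut, tumor_count, kind, extra) -> None:
        actual_wt = protein.residue(pos)
        if actual_wt != wt:
            raise ValidationError(
                f"planted {kind}: {protein.protein_id} pos {pos} is {actual_wt!r}, "
                f"spec says {wt!r}"
            )
        chosen = rng.choice(config.n_samples, size=tumor_count, replace=False)
        for j in sorted(int(x) for x in chosen):
            sample = sample_ids[j]
            add_somatic(protein.protein_id, pos, wt, mut, sample, sample_contexts[sample])
        manifest_rows.append(
            {
                "kind": kind,
                "protein_id": protein.protein_id,
                "position": pos,
                "wt_residue": wt,
                "mut_residue": mut,
                "tumor_count": tumor_count,
                **extra,
            }
        )

    for h in config.planted_hotspots:
        plant_recurrent(
            proteome[h.protein_index], h.position, h.wt_residue, h.mut_residue,
            h.tumor_count, "hotspot", {},
        )
    for ev in config.planted_flank_events:
        protein = proteome[ev.protein_index]
        plant_recurrent(
            protein, ev.site_position + ev.offset, ev.wt_residue, ev.mut_residue,
            ev.tumor_count, "flank_event",
            {
                "site_position": ev.site_position,
                "offset": ev.offset,
                "kinase_name": ev.kinase_name,
            },
        )

    # --- germline variants ---------------------------------------------
    rng = _stream(config.seed, "germline")
    germline: list[MutationRecord] = []
    germline_keys: set[tuple] = set()
    phosphosites = [s for s in sites if s.ptm_type == "phosphorylation"]
    proteome_index = {p.protein_id: p for p in proteome}
    n_mimic = int(round(config.mimic_fraction * config.n_germline))
    attempts = 0
    while len(germline) < config.n_germline and attempts < config.n_germline * 20:
        attempts += 1
        i = len(germline)
        if i < n_mimic and phosphosites:
            site = phosphosites[int(rng.integers(len(phosphosites)))]
            protein_id, pos = site.protein_id, site.position
            wt = site.residue
            mut = "DE"[int(rng.integers(2))]
            kind = "mimic"
        elif rng.random() < config.germline_ptm_targeting and sites:
            site = sites[int(rng.integers(len(sites)))]
            protein = proteome_index[site.protein_id]
            offset = int(rng.integers(-5, 6))
            pos = min(max(site.position + offset, 1), len(protein.sequence))
            protein_id = site.protein_id
            wt = protein.sequence[pos - 1]
            mut = _random_mut(rng, wt)
            kind = None
        else:
            protein = proteome[int(rng.integers(len(proteome)))]
            pos = int(rng.integers(1, len(protein.sequence) + 1))
            protein_id = protein.protein_id
            wt = protein.sequence[pos - 1]
            mut = _random_mut(rng, wt)
            kind = None
        if wt == "X" or wt == mut:
            continue
        key = (protein_id, pos, wt, mut)
        if key in germline_keys:
            continue
        germline_keys.add(key)
        variant_id = f"rs{900000 + len(germline):07d}"
        germline.append(
            MutationRecord(
                protein_id=protein_id,
                position=pos,
                wt_residue=wt,
                mut_residue=mut,
                source=MutationSource.GERMLINE,
                sample_id=variant_id,
                context_label=DISEASE_LABELS[int(rng.integers(len(DISEASE_LABELS)))],
            )
        )
        if kind == "mimic":
            manifest_rows.append(
                {
                    "kind": "mimic",
                    "protein_id": protein_id,
                    "position": pos,
                    "wt_residue": wt,
                    "mut_residue": mut,
                    "variant_id": variant_id,
                }
            )

    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "kind", "protein_id", "position", "wt_residue", "mut_residue",
            "tumor_count", "site_position", "offset", "kinase_name", "variant_id",
        ],
    )
    for col in ("tumor_count", "site_position", "offset"):
        manifest[col] = manifest[col].astype("Int64")
    for col in ("kinase_name", "variant_id"):
        manifest[col] = manifest[col].fillna("")
    return sites, somatic, germline, manifest


DEFAULT_MOTIF_SPECS = (
    MotifSpec("AKT1like", "basophilic", ((-3, "R", 3.0), (-5, "R", 1.5))),
    MotifSpec("MAPKlike", "proline-directed", ((1, "P", 3.0), (-2, "P", 1.0))),
    MotifSpec("CK2like", "acidophilic", ((3, "E", 2.0), (1, "E", 1.5))),
)


def generate_pssm_set(
    seed: int,
    motif_specs: Sequence[MotifSpec] = DEFAULT_MOTIF_SPECS,
    half_width: int = 7,
) -> list[PSSM]:
    """PSSMs with anchor weights planted and small Gaussian noise elsewhere.

    Noise is keyed by (seed, anchor spec), not by kinase name, so two
    matrices sharing a spec and seed have identical weights.
    """
    pssms = []
    for spec in motif_specs:
        for off, _res, _w in spec.anchors:
            if abs(off) > half_width:
                raise ValueError(
                    f"{spec.kinase_name}: anchor offset {off} outside +/-{half_width}"
                )
        rng = np.random.default_rng(
            [seed, zlib.crc32(repr((spec.anchors, spec.noise_sd, half_width)).encode())]
        )
        weights: dict[tuple[int, str], float] = {}
        for off in range(-half_width, half_width + 1):
            for aa in AMINO_ACIDS:
                weights[(off, aa)] = (
                    float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
                )
        for off, res, w in spec.anchors:
            weights[(off, res)] = w
        pssms.append(
            PSSM(
                kinase_name=spec.kinase_name,
                kinase_group=spec.kinase_group,
                half_width=half_width,
                weights=weights,
            )
        )
    return pssms


# ---------------------------------------------------------------------------
# Helpers for picking valid planting spots on a generated proteome

def find_hotspot_spots(
    proteome: Sequence[ProteinRecord],
    seed: int,
    n: int,
    tumor_count: int,
    mut_residue: str | None = None,
) -> list[PlantedHotspot]:
    """Pick ``n`` distinct proteins and one random position in each."""
    rng = _stream(seed, "pick-hotspots")
    if n > len(proteome):
        raise ValueError("more hotspots requested than proteins available")
    indices = sorted(int(i) for i in rng.choice(len(proteome), size=n, replace=False))
    spots = []
    for idx in indices:
        protein = proteome[idx]
        pos = int(rng.integers(1, len(protein.sequence) + 1))
        wt = protein.sequence[pos - 1]
        mut = mut_residue if (mut_residue and mut_residue != wt) else _random_mut(rng, wt)
        spots.append(PlantedHotspot(idx, pos, wt, mut, tumor_count))
    return spots


def find_flank_spots(
    proteome: Sequence[ProteinRecord],
    n: int,
    offset: int,
    flank_wt: str,
    flank_mut: str,
    kinase_name: str = "",
    site_residues: str = "STY",
    tumor_count: int = 3,
) -> list[PlantedFlankEvent]:
    """Scan the proteome for phosphorylatable residues with ``flank_wt`` at
    ``offset`` and return up to ``n`` planting specs (deterministic scan order)."""
    spots: list[PlantedFlankEvent] = []
    for idx, protein in enumerate(proteome):
        seq = protein.sequence
        for pos in range(1, len(seq) + 1):
            if seq[pos - 1] not in site_residues:
                continue
            flank_pos = pos + offset
            if not 1 <= flank_pos <= len(seq):
                continue
            if seq[flank_pos - 1] == flank_wt:
                spots.append(
                    PlantedFlankEvent(
                        protein_index=idx,
                        site_position=pos,
                        offset=offset,
                        wt_residue=flank_wt,
                        mut_residue=flank_mut,
                        kinase_name=kinase_name,
                        tumor_count=tumor_count,
                    )
                )
                if len(spots) == n:
                    return spots
    return spots
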