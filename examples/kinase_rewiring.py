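"""Delta scores: predicted kinase-motif rewiring by flank mutations.

Scores the wild-type and mutated +/-7 flanks of a phosphosite against a
basophilic (AKT-like) matrix that rewards arginine at position -3.  An
R->H substitution there removes the motif anchor: the mutant flank scores
lower and the delta (mut - wt) is negative, a predicted loss of upstream
regulation.  The reverse substitution scores positive (predicted gain).
"""

from ptmut.intersect import find_flank_hits
from ptmut.model import MutationRecord, MutationSource, PTMSite, ProteinRecord
from ptmut.rewiring import build_flank_pairs, delta_score
from ptmut.synthetic import MotifSpec, generate_pssm_set

seq = list("A" * 40)
seq[20 - 1] = "S"   # phosphosite at 20
seq[17 - 1] = "R"   # arginine at -3, the basophilic anchor
protein = ProteinRecord("SYNP", "".join(seq))
site = PTMSite("SYNP", 20, "S", "phosphorylation")
mutation = MutationRecord("SYNP", 17, "R", "H", MutationSource.SOMATIC, "t1")

(akt,) = generate_pssm_set(
    seed=1, motif_specs=[MotifSpec("AKT1like", "basophilic", ((-3, "R", 3.0),),
                                   noise_sd=0.1)]
)

hits = find_flank_hits([mutation], [site])
(pair,) = build_flank_pairs(hits, {"SYNP": protein})
print(f"wt  flank: {pair.wt_flank}")
print(f"mut flank: {pair.mut_flank}")

ds = delta_score(pair, akt)
print(f"\n{akt.kinase_name}: wt {ds.wt_score:+.3f}  mut {ds.mut_score:+.3f}  "
      f"delta {ds.delta:+.3f}")
print("\ndelta < 0: the R17H substitution removes the arginine the basophilic")
print("matrix requires at -3, a predicted loss of kinase binding at S20.")
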