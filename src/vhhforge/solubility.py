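"""Structure-guided solubility engineering heuristic.

Flags exposed hydrophobic residues outside the CDR loops (relative-SASA
threshold; exposure is the single quantitative criterion standing in for
manual inspection of hydrophobic cores) and proposes substitutions in the
spirit of Ile->Ala / Met->Lys.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import AntibodyAnnotation
from .structure import THREE_TO_ONE, StructureModel, sasa

__all__ = [
    "HYDROPHOBIC_SET",
    "DEFAULT_MUTATION_RULE",
    "KD_HYDROPATHY",
    "ExposedCandidate",
    "MutationSuggestion",
    "flag_exposed_hydrophobics",
    "suggest_mutations",
]

# Default hydrophobic set excludes A (mutation target), C (conserved
# disulfide) and borderline Y.
HYDROPHOBIC_SET = frozenset("ILVMFW")

# aliphatic/branched -> Ala; bulky hydrophobic -> Lys
DEFAULT_MUTATION_RULE = {"I": "A", "L": "A", "V": "A", "M": "K", "F": "K", "W": "K"}

# Kyte-Doolittle hydropathy, used only to rank candidates of equal exposure.
KD_HYDROPATHY = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class ExposedCandidate:
    chain: str
    resnum: int
    wt: str              # 1-letter
    rel_sasa: float
    hydropathy: float


@dataclass
class MutationSuggestion:
    chain: str
    resnum: int
    wt: str
    proposed: str
    rel_sasa: float
    hydropathy: float
    reason: str


def flag_exposed_hydrophobics(
    model: StructureModel,
    chain: str,
    annotation: AntibodyAnnotation,
    rel_sasa_min: float = 0.30,
    hydrophobic_set: frozenset = HYDROPHOBIC_SET,
    probe: float = 1.4,
    n_points: int = 960,
) -> list[ExposedCandidate]:
    """Residues on ``chain`` that are hydrophobic, exposed (relative SASA >=
    threshold) and outside every CDR span, sorted by decreasing exposure.

    Annotation spans map onto the chain positionally (span index i <-> i-th
    chain residue).
    """
    if not model.chain_mask(chain).any():
        raise ValueError(f"chain {chain!r} absent from model")
    profile = sasa(model, probe=probe, n_points=n_points)
    chain_residues = [(rn, resname) for c, rn, _, resname, _ in model.residues(chain)]
    cdr_positions = annotation.cdr_index_set()

    candidates = []
    for pos, (resnum, resname) in enumerate(chain_residues):
        one = THREE_TO_ONE.get(resname)
        if one is None or one not in hydrophobic_set:
            continue
        if pos in cdr_positions:
            continue
        rel = profile.residue_rel(chain, resnum)
        if rel >= rel_sasa_min:
            candidates.append(ExposedCandidate(chain, resnum, one, rel,
                                               KD_HYDROPATHY[one]))
    candidates.sort(key=lambda c: (-c.rel_sasa, c.resnum))
    return candidates


def suggest_mutations(candidates, rule: dict | None = None) -> list[MutationSuggestion]:
    """Deterministic substitution proposals for exposed hydrophobics."""
    rule = DEFAULT_MUTATION_RULE if rule is None else rule
    out = []
    for c in candidates:
        proposed = rule.get(c.wt)
        if proposed is None:
            continue
        out.append(MutationSuggestion(
            chain=c.chain, resnum=c.resnum, wt=c.wt, proposed=proposed,
            rel_sasa=c.rel_sasa, hydropathy=c.hydropathy,
            reason=(f"exposed hydrophobic (relSASA {c.rel_sasa:.2f}) outside "
                    f"CDRs; {c.wt}{c.resnum}{proposed}"),
        ))
    return out


def write_suggestions_tsv(suggestions, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresnum\twt\tproposed\trel_sasa\thydropathy\treason\n")
        for s in suggestions:
            fh.write(f"{s.chain}\t{s.resnum}\t{s.wt}\t{s.proposed}\t"
                     f"{s.rel_sasa:.4f}\t{s.hydropathy:.1f}\t{s.reason}\n")
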