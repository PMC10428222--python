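"""Mutation-selection and chimera-construction rules for dual-agonist
peptide design.

The design substrate is the 29-residue human glucagon template. Point
mutations carry "S16W"-style labels (wild-type letter, 1-based position,
mutant letter) and are validated against the current sequence, which
guards against numbering drift. A design rule file lists, in application
order: a mutation set, back-mutations (position -> residue), and an
optional C-terminal graft from a donor sequence (e.g. the GLP-1
C-terminal Arg/Gly pair). Candidates are ranked by a coupled dual-receptor
affinity score: the sum of the two predicted binding free energies,
with the absolute difference reported as a balance diagnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .core import CANONICAL_AA, PeptideSequence, ValidationError
from .energetics import EnergyDecomposition

#: Canonical template and donor sequences shipped with the rule files.
GLUCAGON = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"          # human glucagon, 29-mer
GLP1_7_37 = "HAEGTFTSDVSSYLEGQAAKEFIAWLVKGRG"        # GLP-1(7-37), renumbered 1-31

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution: wild-type *wt* at 1-based *position* -> *mut*."""

    position: int
    wt: str
    mut: str

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValidationError(f"{self.label}: wt equals mut")
        for aa in (self.wt, self.mut):
            if aa not in CANONICAL_AA:
                raise ValidationError(f"{self.label}: non-canonical residue {aa!r}")
        if self.position < 1:
            raise ValidationError(f"{self.label}: position must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, label: str) -> "MutationSpec":
        m = _MUT_RE.match(label.strip().upper())
        if not m:
            raise ValidationError(f"cannot parse mutation label {label!r}")
        return cls(position=int(m.group(2)), wt=m.group(1), mut=m.group(3))


@dataclass(frozen=True)
class GraftSpec:
    """Append donor residues from *donor_from* (1-based) to the donor's end."""

    donor: PeptideSequence
    donor_from: int
    mode: str = "append"

    def __post_init__(self):
        if self.mode != "append":
            raise ValidationError(f"unsupported graft mode {self.mode!r}")
        if not 1 <= self.donor_from <= len(self.donor) + 1:
            raise ValidationError(
                f"graft start {self.donor_from} outside donor 1..{len(self.donor)}"
            )


def apply_mutations(seq: PeptideSequence, muts) -> PeptideSequence:
    """Apply point substitutions; each wt letter must match the sequence."""
    residues = list(seq.residues)
    labels = []
    for mut in muts:
        if mut.position > len(residues):
            raise ValidationError(
                f"{mut.label}: position {mut.position} beyond sequence length {len(residues)}"
            )
        found = residues[mut.position - 1]
        if found != mut.wt:
            raise ValidationError(
                f"{mut.label}: template has {found!r} at position {mut.position}, "
                f"expected {mut.wt!r}"
            )
        residues[mut.position - 1] = mut.mut
        labels.append(mut.label)
    return PeptideSequence(seq.id, "".join(residues),
                           seq.provenance + tuple(labels))


def graft_cterm(seq: PeptideSequence, graft: GraftSpec) -> PeptideSequence:
    """Append the donor's C-terminal residues (donor_from..end)."""
    appended = graft.donor.residues[graft.donor_from - 1:]
    if not appended:
        return seq
    label = f"graft:{graft.donor.id}[{graft.donor_from}:{len(graft.donor)}]"
    return PeptideSequence(seq.id, seq.residues + appended,
                           seq.provenance + (label,))


# ---------------------------------------------------------------------------
# mutation-effect classification
# ---------------------------------------------------------------------------

CLASS_LABELS = ("improves_both", "improves_GCGR", "improves_GLP1R",
                "penalizes", "neutral")


@dataclass(frozen=True)
class MutationClassification:
    """ddG convention: mutant minus reference; negative = better binding."""

    ddg_gcgr: float
    ddg_glp1r: float
    threshold: float
    label: str
    mutation: MutationSpec | None = None


def classify_mutation(ddg_gcgr: float, ddg_glp1r: float,
                      threshold: float = 5.0,
                      mutation: MutationSpec | None = None) -> MutationClassification:
    """Classify a point mutation from its two receptor ddG values (kJ/mol).

    improves_X when ddG_X <= -threshold (both -> improves_both); penalizes
    when either ddG >= +threshold and neither improves; neutral otherwise.
    """
    import math

    if not (math.isfinite(ddg_gcgr) and math.isfinite(ddg_glp1r)):
        raise ValidationError("non-finite ddG")
    imp_gcgr = ddg_gcgr <= -threshold
    imp_glp1r = ddg_glp1r <= -threshold
    if imp_gcgr and imp_glp1r:
        label = "improves_both"
    elif imp_gcgr:
        label = "improves_GCGR"
    elif imp_glp1r:
        label = "improves_GLP1R"
    elif ddg_gcgr >= threshold or ddg_glp1r >= threshold:
        label = "penalizes"
    else:
        label = "neutral"
    return MutationClassification(ddg_gcgr, ddg_glp1r, threshold, label, mutation)


def significant_residues(decomp: EnergyDecomposition,
                         threshold: float = -50.0) -> list:
    """Residue keys whose total contribution is below *threshold* kJ/mol
    (default -50: strongly binding hotspots), ascending by position."""
    return sorted(k for k, v in decomp.per_residue.items() if v["total"] < threshold)


def coupled_affinity(dg_gcgr: float, dg_glp1r: float) -> tuple:
    """(composite, imbalance): composite = sum of the two dG values (lower
    is better dual binding), imbalance = |dG_GCGR - dG_GLP1R| (lower is
    better balanced agonism)."""
    return dg_gcgr + dg_glp1r, abs(dg_gcgr - dg_glp1r)


def rank_candidates(candidates) -> list:
    """Sort (sequence, dg_gcgr, dg_glp1r) triples by composite coupled
    affinity, ties broken by imbalance then sequence id. Deterministic;
    returns a permutation of the input."""
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no candidates to rank")

    def key(item):
        seq, g, l = item
        comp, imb = coupled_affinity(g, l)
        return (comp, imb, seq.id)

    return sorted(candidates, key=key)


# ---------------------------------------------------------------------------
# design rules
# ---------------------------------------------------------------------------

@dataclass
class DesignRules:
    """A named, ordered design recipe parsed from YAML.

    Application order is fixed: mutations, then back-mutations, then the
    optional C-terminal graft.
    """

    name: str
    template: PeptideSequence
    mutations: list
    back_mutations: list  # of (position, residue)
    graft: GraftSpec | None = None


def load_rules(source) -> DesignRules:
    """Load a design-rule YAML from a path, a mapping, or a shipped rule
    name ("mdd_gr", "mdd_gcgr", "mdd_glp1r", "cotadutide")."""
    if isinstance(source, dict):
        doc = source
        name = doc.get("name", "rules")
    else:
        path = Path(str(source))
        if not path.exists():
            pkg_path = resources.files("coagdesign").joinpath(f"rules/{source}.yaml")
            if pkg_path.is_file():
                path = pkg_path
            else:
                raise FileNotFoundError(f"no rule file {source!r}")
        doc = yaml.safe_load(Path(path).read_text())
        name = doc.get("name", Path(path).stem)

    template = PeptideSequence(doc.get("template_id", "template"), doc["template"])
    mutations = [MutationSpec.parse(m) for m in doc.get("mutations", [])]
    back = [(int(b["position"]), str(b["to"]).upper())
            for b in doc.get("back_mutations", [])]
    graft = None
    if doc.get("graft"):
        g = doc["graft"]
        donor = PeptideSequence(g.get("donor_id", "donor"), g["donor"])
        graft = GraftSpec(donor=donor, donor_from=int(g["from"]))
    return DesignRules(name, template, mutations, back, graft)


def build_design(template: PeptideSequence | None, rules) -> PeptideSequence:
    """Run a design recipe: mutations -> back-mutations -> graft.

    *rules* may be a :class:`DesignRules`, a mapping, a rule file path or a
    shipped rule name; *template* overrides the rule file's template when
    given. Provenance records every step. Step failures propagate with the
    step name prefixed.
    """
    if not isinstance(rules, DesignRules):
        rules = load_rules(rules)
    seq = template if template is not None else rules.template
    seq = PeptideSequence(rules.name, seq.residues, seq.provenance)

    try:
        seq = apply_mutations(seq, rules.mutations)
    except ValidationError as exc:
        raise ValidationError(f"mutations: {exc}") from exc

    back_specs = []
    for pos, to in rules.back_mutations:
        wt = seq[pos]
        if wt == to:  # already the target residue; no-op
            continue
        back_specs.append(MutationSpec(position=pos, wt=wt, mut=to))
    try:
        seq = apply_mutations(seq, back_specs)
    except ValidationError as exc:
        raise ValidationError(f"back_mutations: {exc}") from exc

    if rules.graft is not None:
        try:
            seq = graft_cterm(seq, rules.graft)
        except ValidationError as exc:
            raise ValidationError(f"graft: {exc}") from exc
    return seq
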