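"""Synthetic precursor libraries and labelled cage datasets.

The generator mirrors the combinatorial structure of the study system:
a library of tritopic and ditopic precursor cores, each functionalised
with the reactive group a reaction chemistry requires (aldehyde, amine,
acid, alkene, alkyne), paired exhaustively — every tritopic x ditopic
combination — within each of six reaction families.

Labels are planted through a known structural mechanism so that model and
attribution behaviour can be validated against ground truth: a fraction of
cores are built from flexible aliphatic motifs and flagged as "collapse
cores", and the collapse probability of a cage is a logistic function of
(i) how many of its two precursors are collapse cores and (ii) the number
of rotatable aliphatic bonds in its linker.  This encodes the chemical
expectation that saturated aliphatic chains, with their internal degrees
of freedom, drive the loss of shape persistence.  A configurable fraction
of records is then relabelled "undetermined" uniformly at random
(mimicking cages whose geometry supports neither call; they are excluded
from modelling downstream).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .model import COLLAPSED, NOT_COLLAPSED
from .train_eval import REACTION_FAMILIES, CageRecord

__all__ = [
    "GROUP_SMILES",
    "REACTION_GROUPS",
    "PrecursorTemplate",
    "PrecursorLibrary",
    "PlantedRule",
    "generate_precursors",
    "enumerate_cages",
    "plant_labels",
    "generate_dataset",
    "rotatable_aliphatic_bonds",
]

#: Attachable SMILES fragment per functional-group tag (written so that the
#: first character is an atom, valid both as a branch and as a suffix).
GROUP_SMILES: dict[str, str] = {
    "aldehyde": "C=O",
    "amine": "N",
    "acid": "C(=O)O",
    "alkene": "C=C",
    "alkyne": "C#C",
}

#: reaction family -> (building-block group, linker group)
REACTION_GROUPS: dict[str, tuple[str, str]] = {
    "aldehyde3amine2": ("aldehyde", "amine"),
    "amine3aldehyde2": ("amine", "aldehyde"),
    "alkene3alkene2": ("alkene", "alkene"),
    "alkyne3alkyne2": ("alkyne", "alkyne"),
    "acid3amine2": ("acid", "amine"),
    "amine3acid2": ("amine", "acid"),
}

# Motif grammar: format strings with one slot per attachment site.  Rigid
# motifs are (hetero)aromatic or alicyclic cores; flexible motifs have an
# aliphatic centre or backbone and are the designated collapse cores.
_TRI_RIGID = (
    "c1c({0})cc({1})cc1{2}",                       # benzene-1,3,5
    "c1({0})nc({1})nc({2})n1",                     # 1,3,5-triazine
    "c1cc({0})cc(-c2cc({1})cc({2})c2)c1",          # tritopic biphenyl
)
_TRI_FLEX = (
    "C({0})({1}){2}",                              # central methine
    "N({0})({1}){2}",                              # central amine
    "CC({0})(C{1})C{2}",                           # quaternary neopentyl
)
_DI_RIGID = (
    "c1cc({0})ccc1{1}",                            # benzene-1,4
    "c1cc({0})cc({1})c1",                          # benzene-1,3
    "c1cc({0})ccc1-c1ccc({1})cc1",                 # biphenyl-4,4'
    "c1cc({0})ncc1{1}",                            # pyridine
    "c1cc({0})sc1{1}",                             # thiophene
    "c1cc({0})oc1{1}",                             # furan
    "C1CC({0})CCC1{1}",                            # cyclohexane-1,4
    "c1cc({0})ccc1C#Cc1ccc({1})cc1",               # alkyne-bridged diphenyl
    "c1cc({0})ccc1Oc1ccc({1})cc1",                 # diphenyl ether
)
_DI_FLEX = (
    "C({0})C{1}",                                  # methylene chain
    "C({0})COC{1}",                                # ether chain
    "C({0})CSC{1}",                                # thioether chain
    "C(C{0})(C)C{1}",                              # gem-methyl-branched chain
    "C({0})CN(C)C{1}",                             # N-methyl amine chain
)

_RIGID_SPACERS = (0, 1, 2, 3)      # methylene spacer lengths per site
_FLEX_SPACERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class PrecursorTemplate:
    """A core scaffold with attachment sites, before functionalisation.

    ``core`` is a SMILES format string with one slot per site; each site
    carries a methylene spacer of the stated length between the core and
    the functional group.  ``tag`` is set once a group is attached.
    """

    core: str
    topicity: int
    spacers: tuple[int, ...]
    collapse_core: bool
    tag: str | None = None

    def __post_init__(self) -> None:
        if len(self.spacers) != self.topicity:
            raise ValueError("one spacer length per attachment site required")

    def functionalise(self, group: str) -> str:
        """SMILES of the precursor with ``group`` at every site."""
        frag = GROUP_SMILES[group]
        slots = ["C" * s + frag for s in self.spacers]
        return self.core.format(*slots)


@dataclass
class PrecursorLibrary:
    """Generated tritopic and ditopic templates plus ground-truth flags."""

    tritopic: list[PrecursorTemplate]
    ditopic: list[PrecursorTemplate]
    seed: int
    _flag_cache: dict[str, bool] = field(default_factory=dict, repr=False)

    def templates(self, topicity: int) -> list[PrecursorTemplate]:
        if topicity == 3:
            return self.tritopic
        if topicity == 2:
            return self.ditopic
        raise ValueError("topicity must be 2 or 3")

    def _build_flag_cache(self) -> None:
        for tpl in self.tritopic + self.ditopic:
            for group in GROUP_SMILES:
                smi = tpl.functionalise(group)
                self._flag_cache[Chem.CanonSmiles(smi)] = tpl.collapse_core

    def is_collapse_core(self, smiles: str) -> bool:
        """Ground-truth flag for a functionalised precursor SMILES."""
        if not self._flag_cache:
            self._build_flag_cache()
        return self._flag_cache[Chem.CanonSmiles(smiles)]


def _enumerate_templates(
    motifs: Sequence[str],
    topicity: int,
    spacer_range: Sequence[int],
    collapse_core: bool,
) -> list[PrecursorTemplate]:
    """All (motif, spacer assignment) combinations, deduplicated by the
    canonical SMILES of an amine-functionalised reference molecule."""
    out, seen = [], set()
    for motif in motifs:
        for spacers in itertools.product(spacer_range, repeat=topicity):
            tpl = PrecursorTemplate(motif, topicity, spacers, collapse_core)
            smi = tpl.functionalise("amine")
            mol = Chem.MolFromSmiles(smi)
            if mol is None:  # grammar bug guard; motifs are all valid
                raise ValueError(f"motif grammar produced invalid SMILES {smi!r}")
            canon = Chem.MolToSmiles(mol)
            if canon not in seen:
                seen.add(canon)
                out.append(tpl)
    return out


def generate_precursors(
    n_tritopic: int,
    n_ditopic: int,
    seed: int = 0,
    collapse_core_fraction: float = 0.3,
) -> PrecursorLibrary:
    """Sample a deterministic precursor library from the motif grammar.

    ``collapse_core_fraction`` of each topicity is drawn from the flexible
    (aliphatic) motif subset and flagged as ground-truth collapse cores;
    the remainder come from the rigid subset.
    """
    if n_tritopic < 1 or n_ditopic < 1:
        raise ValueError("library needs at least one precursor per topicity")
    if not 0 <= collapse_core_fraction <= 1:
        raise ValueError("collapse_core_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def sample(n: int, rigid_motifs, flex_motifs, topicity) -> list[PrecursorTemplate]:
        rigid = _enumerate_templates(rigid_motifs, topicity, _RIGID_SPACERS, False)
        flex = _enumerate_templates(flex_motifs, topicity, _FLEX_SPACERS, True)
        k_flex = int(round(collapse_core_fraction * n))
        k_rigid = n - k_flex
        if k_flex > len(flex) or k_rigid > len(rigid):
            raise ValueError(
                f"grammar exhausted: requested {k_rigid} rigid / {k_flex} "
                f"flexible, available {len(rigid)} / {len(flex)}"
            )
        chosen = [rigid[i] for i in rng.permutation(len(rigid))[:k_rigid]]
        chosen += [flex[i] for i in rng.permutation(len(flex))[:k_flex]]
        order = rng.permutation(len(chosen))
        return [chosen[i] for i in order]

    return PrecursorLibrary(
        tritopic=sample(n_tritopic, _TRI_RIGID, _TRI_FLEX, 3),
        ditopic=sample(n_ditopic, _DI_RIGID, _DI_FLEX, 2),
        seed=seed,
    )


def enumerate_cages(
    library: PrecursorLibrary,
    reactions: Iterable[str] = REACTION_FAMILIES,
) -> list[CageRecord]:
    """Full Cartesian pairing of tritopic x ditopic precursors per reaction.

    Every reaction family pairs each functionalised building block with
    each functionalised linker, so a library of T tritopic and D ditopic
    cores yields ``T * D`` cages per reaction.
    """
    reactions = list(reactions)
    for r in reactions:
        if r not in REACTION_GROUPS:
            raise ValueError(f"unknown reaction family {r!r}")
    records = []
    for reaction in reactions:
        bb_group, lk_group = REACTION_GROUPS[reaction]
        bbs = [t.functionalise(bb_group) for t in library.tritopic]
        lks = [t.functionalise(lk_group) for t in library.ditopic]
        for i, bb in enumerate(bbs):
            for j, lk in enumerate(lks):
                records.append(
                    CageRecord(
                        bb_smiles=bb,
                        linker_smiles=lk,
                        reaction=reaction,
                        label=None,
                        cage_id=f"{reaction}-{i:03d}-{j:03d}",
                    )
                )
    return records


def rotatable_aliphatic_bonds(smiles: str) -> int:
    """Count acyclic single bonds between non-terminal aliphatic carbons.

    This is the flexibility measure of the planted mechanism: each such
    bond is an internal rotational degree of freedom of a saturated chain.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if all(
            at.GetSymbol() == "C" and not at.GetIsAromatic() and at.GetDegree() >= 2
            for at in (a, b)
        ):
            count += 1
    return count


@dataclass(frozen=True)
class PlantedRule:
    """Logistic ground-truth collapse mechanism.

    collapse probability = sigmoid(intercept
                                   + w_core * #collapse-core precursors
                                   + w_flex * rotatable aliphatic bonds
                                              in the linker)

    Defaults are calibrated so that, with the default library settings,
    the class mix approximates the study's 47% collapsed / 34% not
    collapsed / 19% undetermined once the undetermined fraction is
    injected.
    """

    intercept: float = -2.1
    w_core: float = 1.2
    w_flex: float = 0.5
    noise_seed: int = 0

    def probability(self, n_cores: int, linker_flex: int) -> float:
        z = self.intercept + self.w_core * n_cores + self.w_flex * linker_flex
        if not math.isfinite(z):
            raise ValueError("planted rule produced non-finite logit")
        return 1.0 / (1.0 + math.exp(-z))


def plant_labels(
    records: Sequence[CageRecord],
    rule: PlantedRule,
    library: PrecursorLibrary,
    seed: int = 0,
    undetermined_fraction: float = 0.195,
) -> tuple[list[CageRecord], pd.DataFrame]:
    """Draw labels from the planted rule; return records + ground truth.

    Labels are Bernoulli draws from the rule's collapse probability; a
    uniformly random ``undetermined_fraction`` of records is then
    relabelled "undetermined".  The ground-truth table (per-cage
    probability, core flags, linker flexibility) is returned separately
    for recovery experiments and never leaks into the records.
    """
    if not 0 <= undetermined_fraction < 1:
        raise ValueError("undetermined_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed if rule.noise_seed == 0 else rule.noise_seed)
    flex_cache: dict[str, int] = {}
    rows = []
    labelled: list[CageRecord] = []
    for rec in records:
        bb_core = library.is_collapse_core(rec.bb_smiles)
        lk_core = library.is_collapse_core(rec.linker_smiles)
        if rec.linker_smiles not in flex_cache:
            flex_cache[rec.linker_smiles] = rotatable_aliphatic_bonds(
                rec.linker_smiles
            )
        flex = flex_cache[rec.linker_smiles]
        p = rule.probability(int(bb_core) + int(lk_core), flex)
        label = COLLAPSED if rng.random() < p else NOT_COLLAPSED
        labelled.append(rec.with_label(label))
        rows.append(
            {
                "cage_id": rec.cage_id,
                "p_collapse": p,
                "bb_collapse_core": bb_core,
                "linker_collapse_core": lk_core,
                "linker_flex": flex,
            }
        )
    n_und = int(round(undetermined_fraction * len(labelled)))
    und_idx = rng.choice(len(labelled), size=n_und, replace=False)
    for i in und_idx:
        labelled[i] = replace(labelled[i], label="undetermined")
    truth = pd.DataFrame(rows)
    truth["label"] = [r.label for r in labelled]
    return labelled, truth


def generate_dataset(
    n_tritopic: int = 12,
    n_ditopic: int = 28,
    seed: int = 0,
    reactions: Iterable[str] = REACTION_FAMILIES,
    rule: PlantedRule | None = None,
    collapse_core_fraction: float = 0.3,
    undetermined_fraction: float = 0.195,
) -> tuple[list[CageRecord], pd.DataFrame, PrecursorLibrary]:
    """Library -> enumeration -> planted labels, in one deterministic call."""
    library = generate_precursors(
        n_tritopic, n_ditopic, seed=seed,
        collapse_core_fraction=collapse_core_fraction,
    )
    records = enumerate_cages(library, reactions)
    rule = rule or PlantedRule()
    labelled, truth = plant_labels(
        records, rule, library, seed=seed + 1,
        undetermined_fraction=undetermined_fraction,
    )
    return labelled, truth, library
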