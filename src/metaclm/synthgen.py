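"""Seed-reproducible synthetic activity classes with analogue-series
structure and controllable activity-cliff content.

Each class is built from drug-like scaffold cores with marked
substitution sites; enumerating core x substituent combinations yields
analogue series by construction. Potency follows an additive
substituent-effect model: pKi = base + sum of per-substituent effects +
Gaussian noise. Effects are spread over a range chosen so that the
fraction of analogue pairs crossing the 100-fold activity-cliff
threshold matches a target cliff rate, and so the achievable potency
differences span at least [0, 3] pKi units.

:func:`make_meta_family` draws per-class effects as a shared component
plus a class-specific component, producing related-but-distinct tasks —
the structure meta-learning exploits. Setting the shared component's
scale to zero yields unrelated tasks (the negative control).

Emitted records pass the curation filters by construction, so the whole
pipeline — curation, analogue-pair enumeration, training, evaluation —
runs end to end without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .chem import InvalidStructureError
from .curation import RawActivityRecord

# Scaffold cores, 9-10 heavy atoms, one marked substitution site each.
# Kept compact so token sequences stay short at desk scale; every core
# satisfies the 2:1 core/substituent size rule against the largest pool
# substituent (4 heavy atoms). Scaffolds are fused bicyclics or G-phenyl
# groups whose defining fragment G is NOT itself a pool substituent —
# otherwise two different core+substituent assemblies can collide into
# the same molecule with two different designed potencies.
DEFAULT_CORES: tuple[str, ...] = (
    "c1ccc2nc([*:1])ccc2c1",           # quinoline
    "c1ccc2oc([*:1])nc2c1",            # benzoxazole
    "c1ccc2sc([*:1])nc2c1",            # benzothiazole
    "c1ccc2[nH]c([*:1])nc2c1",         # benzimidazole
    "c1ccc2c(c1)c([*:1])c[nH]2",       # indole (3-substituted)
    "c1ccc2[nH]c([*:1])cc2c1",         # indole (2-substituted)
    "c1ccc2cc([*:1])ccc2c1",           # naphthalene
    "c1ccc2c(c1)cc([*:1])o2",          # benzofuran
    "c1ccc2c(c1)cc([*:1])s2",          # benzothiophene
    "c1ccc2nc([*:1])cnc2c1",           # quinoxaline
    "NS(=O)(=O)c1ccc([*:1])cc1",       # benzenesulfonamide
    "CS(=O)c1ccc([*:1])cc1",           # methylsulfinylbenzene
    "CC(=O)Nc1ccc([*:1])cc1",          # acetanilide
    "CNC(=O)c1ccc([*:1])cc1",          # N-methylbenzamide
    "COC(=O)c1ccc([*:1])cc1",          # methyl benzoate
    "Cn1cnc2ccc([*:1])cc21",           # N-methylbenzimidazole
    "c1ccc2cc([*:1])cnc2c1",           # quinoline (3-substituted)
    "c1ccc2c([*:1])ccnc2c1",           # quinoline (4-substituted)
    "c1cc2ncccc2cc1[*:1]",             # quinoline (6-substituted)
    "c1ccc2c([*:1])cccc2c1",           # naphthalene (1-substituted)
    "c1cc2cc[nH]c2cc1[*:1]",           # indole (5-substituted)
    "c1cc2[nH]cnc2cc1[*:1]",           # benzimidazole (5-substituted)
    "c1ccc2c(c1)c([*:1])cs2",          # benzothiophene (3-substituted)
    "c1ccc2c(c1)c([*:1])co2",          # benzofuran (3-substituted)
)

# Monovalent substituents, 1-4 heavy atoms.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C",
    "F", "Cl", "Br", "I",
    "O", "OC", "OCC", "OC(C)C",
    "N", "NC", "N(C)C", "NCC",
    "C#N", "C=C", "C#C", "CO",
    "C(=O)C", "C(=O)N", "[N+](=O)[O-]", "C(F)(F)F",
)


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic data set."""

    n_classes: int = 2
    cores: tuple[str, ...] = DEFAULT_CORES
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    n_series_per_class: int = 3
    n_substituents_per_series: int = 12
    base_pki: float = 5.0
    substituent_effects: dict[str, float] | None = None
    noise_sd: float = 0.1
    cliff_rate: float = 0.2
    n_replicates: int = 1
    replicate_sd: float = 0.05  # within one order of magnitude: survives curation
    # When selecting the per-series substituent subset from the
    # effect-ordered pool, skip this fraction at both extremes. A small
    # margin keeps the subset's pairwise effect gaps away from the noise-
    # stretched tails, which controls how many pairs per series cross the
    # activity-cliff threshold.
    substituent_margin: float = 0.0
    seed: int = 0

    def effect_range(self) -> float:
        """Effect span making the expected analogue-pair cliff fraction
        approximate ``cliff_rate``: for effects uniform on [0, E], the
        fraction of pairs with |difference| >= 2 is (1 - 2/E)^2."""
        if not 0 < self.cliff_rate < 1:
            raise ValueError("cliff_rate must be in (0, 1)")
        e = 2.0 / (1.0 - math.sqrt(self.cliff_rate))
        return max(e, 3.0)  # achievable potency differences span >= [0, 3]

    def with_(self, **overrides) -> "SynthSpec":
        return replace(self, **overrides)


# ----------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------

def _site_numbers(core: Chem.Mol) -> list[int]:
    return sorted(a.GetAtomMapNum() for a in core.GetAtoms()
                  if a.GetAtomicNum() == 0)


def assemble(core_smiles: str, substituents: dict[int, str]) -> str:
    """Attach one substituent fragment per marked site of a scaffold core.

    ``substituents`` maps site number (the atom-map number of the core's
    attachment dummy) to a plain fragment SMILES whose first atom binds
    the core. Returns the canonical SMILES of the assembled molecule.
    """
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise InvalidStructureError(f"unparsable core: {core_smiles!r}")
    sites = _site_numbers(core)
    if sorted(substituents) != sites:
        raise ValueError(f"core {core_smiles!r} has sites {sites}, "
                         f"got substituents for {sorted(substituents)}")
    combined = core
    for site, frag_smiles in substituents.items():
        frag = Chem.MolFromSmiles(f"[*:{site}]{frag_smiles}")
        if frag is None:
            raise InvalidStructureError(
                f"unparsable substituent {frag_smiles!r} for core "
                f"{core_smiles!r} at site {site}")
        combined = Chem.CombineMols(combined, frag)
    zipped = Chem.molzip(combined)
    try:
        Chem.SanitizeMol(zipped)
    except Exception as exc:
        raise InvalidStructureError(
            f"invalid assembly of core {core_smiles!r} with "
            f"{substituents!r}: {exc}") from exc
    return Chem.MolToSmiles(zipped)


def _evenly_spaced_subset(items: list[str], m: int,
                          margin: float = 0.0) -> list[str]:
    """m items spread evenly across a list ordered by effect size, so a
    series' pairwise effect differences keep the pool's cliff fraction.
    ``margin`` trims that fraction of positions at each extreme first."""
    if m >= len(items):
        return list(items)
    lo = margin * (len(items) - 1)
    hi = (1.0 - margin) * (len(items) - 1)
    idx = np.unique(np.round(np.linspace(lo, hi, m)).astype(int))
    i = 0
    while len(idx) < m:  # repair collisions from rounding
        if i not in idx:
            idx = np.sort(np.append(idx, i))
        i += 1
    return [items[i] for i in idx]


def default_effects(spec: SynthSpec, rng: np.random.Generator) -> dict[str, float]:
    """Evenly spaced effects over [0, E], assigned to a shuffled pool."""
    pool = list(spec.substituent_pool)
    effects = np.linspace(0.0, spec.effect_range(), len(pool))
    order = rng.permutation(len(pool))
    return {pool[i]: float(effects[j]) for j, i in enumerate(order)}


# ----------------------------------------------------------------------
# Generation
# ----------------------------------------------------------------------

def _class_records(class_id: str, cores: list[str],
                   effects: dict[str, float], spec: SynthSpec,
                   rng: np.random.Generator) -> list[RawActivityRecord]:
    by_effect = sorted(effects, key=lambda s: effects[s])
    records: list[RawActivityRecord] = []
    for core in cores:
        subs = _evenly_spaced_subset(by_effect, spec.n_substituents_per_series,
                                     spec.substituent_margin)
        site_numbers = _site_numbers(Chem.MolFromSmiles(core))
        for sub in subs:
            smiles = assemble(core, {site_numbers[0]: sub}) \
                if len(site_numbers) == 1 else assemble(
                    core, {s: sub for s in site_numbers})
            pki = spec.base_pki + effects[sub] * len(site_numbers) \
                + rng.normal(0.0, spec.noise_sd)
            for _ in range(spec.n_replicates):
                noisy = pki if spec.n_replicates == 1 else \
                    pki + rng.normal(0.0, spec.replicate_sd)
                records.append(RawActivityRecord(
                    compound_structure=smiles, target_id=class_id,
                    relationship_type="D", confidence_score=9,
                    measurement_type="Ki", potency_pki=float(noisy)))
    return records


def generate_classes(spec: SynthSpec) -> list[RawActivityRecord]:
    """Emit raw activity records for ``spec.n_classes`` synthetic classes.

    Every record carries the metadata the curation filters require
    (relationship "D", confidence 9, Ki), so curation retains the data
    unchanged. Deterministic for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[RawActivityRecord] = []
    for c in range(spec.n_classes):
        effects = spec.substituent_effects or default_effects(spec, rng)
        cores = [spec.cores[(c * spec.n_series_per_class + i) % len(spec.cores)]
                 for i in range(spec.n_series_per_class)]
        records.extend(_class_records(f"T{c:02d}", cores, effects, spec, rng))
    return records


def make_meta_family(spec: SynthSpec, shared_effect_scale: float = 1.0,
                     class_effect_sd: float = 0.25, seed: int | None = None,
                     class_offset: int = 0) -> list[RawActivityRecord]:
    """A family of related activity classes for meta-learning experiments.

    Per-class substituent effects are a convex blend of one shared effect
    assignment and a class-specific assignment, plus Gaussian
    perturbation: ``scale * shared + (1 - scale) * own + N(0, sd)``.
    ``shared_effect_scale = 1`` gives closely related tasks;
    ``shared_effect_scale = 0`` gives unrelated tasks with the same
    marginal effect spread (the negative control).

    The shared component depends only on the seed, and each class's own
    component only on (seed, class index + ``class_offset``), so held-out
    classes of one family can be generated in a separate call (e.g. with
    a different series geometry) without replicating a training class.
    """
    if not 0 <= shared_effect_scale <= 1:
        raise ValueError("shared_effect_scale must be in [0, 1]")
    seed0 = spec.seed if seed is None else seed
    shared = default_effects(spec, np.random.default_rng([seed0, 0]))
    records: list[RawActivityRecord] = []
    for c in range(spec.n_classes):
        ci = c + class_offset
        crng = np.random.default_rng([seed0, 1 + ci])
        own = default_effects(spec, crng)
        effects = {s: shared_effect_scale * shared[s]
                   + (1.0 - shared_effect_scale) * own[s]
                   + crng.normal(0.0, class_effect_sd)
                   for s in spec.substituent_pool}
        cores = [spec.cores[(ci * spec.n_series_per_class + i) % len(spec.cores)]
                 for i in range(spec.n_series_per_class)]
        records.extend(_class_records(f"T{ci:02d}", cores, effects, spec, crng))
    return records
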