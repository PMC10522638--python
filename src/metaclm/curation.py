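"""Curation of raw activity records into target-based activity classes.

Raw records (SMILES, target, assay metadata, pKi) are filtered down to
high-confidence equilibrium-constant measurements: direct interactions
(relationship type "D"), the top assay confidence score (9), and Ki-type
measurements only. Replicate measurements for the same compound/target
are aggregated as the geometric mean of Ki — equivalently the arithmetic
mean of pKi — provided they all fall within one order of magnitude on the
Ki scale (a spread of at most 1.0 pKi unit, boundary inclusive);
otherwise the compound is discarded. Qualifying compounds are grouped
into per-target activity classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import compound_id, try_canonical_smiles

log = logging.getLogger(__name__)


class _Discard:
    """Sentinel for compounds rejected by the aggregation spread rule."""

    def __repr__(self) -> str:
        return "DISCARD"


DISCARD = _Discard()


@dataclass(frozen=True)
class RawActivityRecord:
    compound_structure: str
    target_id: str
    relationship_type: str = "D"
    confidence_score: int = 9
    measurement_type: str = "Ki"
    potency_pki: float = float("nan")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    structure: str  # canonical SMILES
    pki: float


@dataclass
class ActivityClass:
    target_id: str
    members: list[CompoundRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CurationConfig:
    relationship_type: str = "D"
    confidence_score: int = 9
    measurement_type: str = "Ki"
    max_pki_spread: float = 1.0  # one order of magnitude on the Ki scale
    human_targets_only: bool = True  # inert unless records carry an organism field


def filter_records(records: list[RawActivityRecord],
                   config: CurationConfig | None = None) -> list[RawActivityRecord]:
    """Keep direct-interaction, confidence-9, Ki records with valid structures.

    Records whose structure does not parse are dropped with a logged
    warning rather than raising; input order is preserved.
    """
    config = config or CurationConfig()
    kept: list[RawActivityRecord] = []
    for rec in records:
        if rec.relationship_type != config.relationship_type:
            continue
        if rec.confidence_score != config.confidence_score:
            continue
        if rec.measurement_type != config.measurement_type:
            continue
        if not np.isfinite(rec.potency_pki):
            log.warning("dropping record with non-finite pKi: %r", rec)
            continue
        if try_canonical_smiles(rec.compound_structure) is None:
            log.warning("dropping record with unparsable structure: %r",
                        rec.compound_structure)
            continue
        kept.append(rec)
    return kept


def aggregate_potency(values: list[float],
                      max_spread: float = 1.0) -> float | _Discard:
    """Aggregate replicate pKi measurements for one compound.

    Returns the arithmetic mean of the pKi values — identical to the
    negative log10 of the geometric mean of the underlying Ki values —
    when the spread max-min is at most ``max_spread`` pKi units
    (inclusive). A larger spread returns :data:`DISCARD`.
    """
    if not values:
        raise ValueError("no potency measurements to aggregate")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite potency measurement")
    if arr.max() - arr.min() > max_spread:
        return DISCARD
    return float(np.sort(arr).mean())  # sorted: exactly permutation-invariant


def build_activity_classes(records: list[RawActivityRecord],
                           config: CurationConfig | None = None
                           ) -> list[ActivityClass]:
    """Partition filtered records into per-target classes of curated compounds.

    Records are grouped by (canonical structure, target); replicate
    measurements are aggregated, and compounds failing the spread rule
    are dropped. Classes are ordered by target id; members by structure.
    """
    config = config or CurationConfig()
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        canon = try_canonical_smiles(rec.compound_structure)
        if canon is None:
            log.warning("skipping unparsable structure: %r", rec.compound_structure)
            continue
        groups.setdefault((rec.target_id, canon), []).append(rec.potency_pki)

    classes: dict[str, ActivityClass] = {}
    for (target, canon), values in sorted(groups.items()):
        pki = aggregate_potency(values, config.max_pki_spread)
        if pki is DISCARD:
            log.info("discarding %s on %s: pKi spread %.2f > %.2f",
                     canon, target, max(values) - min(values),
                     config.max_pki_spread)
            continue
        cls = classes.setdefault(target, ActivityClass(target_id=target))
        cls.members.append(CompoundRecord(compound_id(canon), canon, float(pki)))
    return [classes[t] for t in sorted(classes)]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_COLUMNS = ["smiles", "target_id", "relationship_type", "confidence", "type", "pki"]


def read_activity_table(path: str | Path, sep: str | None = None
                        ) -> list[RawActivityRecord]:
    """Read raw activity records from a TSV/CSV table.

    Expected columns: smiles, target_id, relationship_type, confidence,
    type, pki. The delimiter is inferred from the file suffix unless
    given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity table {path} missing columns: {sorted(missing)}")
    return [RawActivityRecord(compound_structure=str(r.smiles),
                              target_id=str(r.target_id),
                              relationship_type=str(r.relationship_type),
                              confidence_score=int(r.confidence),
                              measurement_type=str(r.type),
                              potency_pki=float(r.pki))
            for r in df.itertuples(index=False)]


def write_activity_table(records: list[RawActivityRecord], path: str | Path) -> None:
    df = pd.DataFrame({
        "smiles": [r.compound_structure for r in records],
        "target_id": [r.target_id for r in records],
        "relationship_type": [r.relationship_type for r in records],
        "confidence": [r.confidence_score for r in records],
        "type": [r.measurement_type for r in records],
        "pki": [r.potency_pki for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def read_activity_sdf(path: str | Path) -> list[RawActivityRecord]:
    """Read records from an SD file, mapping SD tags onto the table columns."""
    from rdkit import Chem

    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            log.warning("skipping unparsable SDF entry in %s", path)
            continue
        props = mol.GetPropsAsDict()
        records.append(RawActivityRecord(
            compound_structure=Chem.MolToSmiles(mol),
            target_id=str(props.get("target_id", "")),
            relationship_type=str(props.get("relationship_type", "D")),
            confidence_score=int(props.get("confidence", 9)),
            measurement_type=str(props.get("type", "Ki")),
            potency_pki=float(props["pki"]),
        ))
    return records


def write_classes(classes: list[ActivityClass], out_dir: str | Path) -> Path:
    """Write one TSV per class plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for cls in classes:
        fname = f"class_{cls.target_id}.tsv"
        df = pd.DataFrame({
            "compound_id": [m.compound_id for m in cls.members],
            "smiles": [m.structure for m in cls.members],
            "pki": [m.pki for m in cls.members],
        })
        df.to_csv(out_dir / fname, sep="\t", index=False)
        manifest.append({"class_id": cls.target_id, "n_members": len(cls),
                         "file": fname})
    manifest_path = out_dir / "classes.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
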