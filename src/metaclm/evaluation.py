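"""Leakage-free test-set construction, compound categorisation, KTC
reproducibility scoring, and statistical comparison of model arms.

A class's activity-cliff (AC_CCR) triples are split 80/20 into
fine-tuning and test instances, resampling until no core structure is
shared between the two sides. CCR triples whose core occurs in the
fine-tuning set are excluded, the remainder joins the test side. Unique
test compounds are categorised at the 1 uM potency threshold: source
compounds (SCs) have pKi <= 6, known target compounds (KTCs) have
pKi > 6. A model reproduces an SC-KTC pair when the KTC's canonical
structure appears among the candidates sampled for that SC;
reproducibility is the percentage of a class's unique KTCs regenerated.
Arms are compared with independent-samples (Welch) t-tests, annotated
with the conventional significance stars.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .ccr import AnaloguePairTriple, PairCategory
from .clm import GenerationResult
from .curation import CompoundRecord

log = logging.getLogger(__name__)

SC_PKI_MAX = 6.0  # 1 uM: SCs have pKi <= 6, KTCs pKi > 6


class PartitionError(RuntimeError):
    pass


@dataclass
class TestPartition:
    class_id: str
    finetune_triples: list[AnaloguePairTriple]
    test_ac_triples: list[AnaloguePairTriple]
    test_ccr_triples: list[AnaloguePairTriple]
    sources: list[CompoundRecord]       # unique test compounds, pKi <= 6
    known_targets: list[CompoundRecord]  # unique test compounds, pKi > 6
    n_overlapping: int  # compounds occurring in both CCR and AC-CCR test pairs

    @property
    def test_triples(self) -> list[AnaloguePairTriple]:
        return self.test_ac_triples + self.test_ccr_triples


@dataclass
class EvaluationReport:
    class_id: str
    fraction: float
    arm: str  # "Meta-CLM" or "CLM"
    n_sc_ktc_pairs: int
    n_unique_ktc: int
    reproducibility_pct: float
    n_novel_candidates: int
    ktc_pki_values: list[float] = field(default_factory=list)
    sc_ktc_delta_values: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SignificanceAnnotation:
    p_value: float
    stars: str

    THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_from_p(p: float) -> str:
    """Significance stars at the conventional boundary-inclusive cuts:
    p <= 0.0001 '****', <= 0.001 '***', <= 0.01 '**', <= 0.05 '*', else 'ns'."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    for cut, label in SignificanceAnnotation.THRESHOLDS:
        if p <= cut:
            return label
    return "ns"


# ----------------------------------------------------------------------
# Partitioning
# ----------------------------------------------------------------------

def _unique_compounds(triples: list[AnaloguePairTriple]) -> dict[str, CompoundRecord]:
    out: dict[str, CompoundRecord] = {}
    for t in triples:
        out.setdefault(t.source.structure, t.source)
        out.setdefault(t.target.structure, t.target)
    return out


def partition_class(ac_triples: list[AnaloguePairTriple],
                    ccr_triples: list[AnaloguePairTriple],
                    seed: int = 0, test_fraction: float = 0.2,
                    max_retries: int = 100000,
                    class_id: str = "") -> TestPartition:
    """Split a class's AC triples into fine-tuning and test sets with no
    shared core, then assemble the final test set.

    Random 80/20 splits (each pair drawn to the test side with
    probability ``test_fraction``, so the ratio holds in expectation) are
    redrawn until the fine-tuning and test AC triples share no core
    structure; after ``max_retries`` failures a :class:`PartitionError`
    reports the colliding cores. CCR triples sharing a core with the
    fine-tuning set are dropped; the remainder joins the test side.
    Unique test compounds are categorised SC/KTC at pKi 6 (a compound at
    exactly 6.0 is an SC).
    """
    if not ac_triples:
        raise ValueError("class has no AC_CCR triples to partition")
    rng = np.random.default_rng(seed)
    colliding: set[str] = set()
    for _ in range(max_retries):
        to_test = rng.random(len(ac_triples)) < test_fraction
        if to_test.all() or not to_test.any():
            continue  # both sides must be populated
        test_ac = [t for t, m in zip(ac_triples, to_test) if m]
        finetune = [t for t, m in zip(ac_triples, to_test) if not m]
        ft_cores = {t.core for t in finetune}
        overlap = {t.core for t in test_ac} & ft_cores
        if not overlap:
            break
        colliding |= overlap
    else:
        raise PartitionError(
            f"no core-disjoint fine-tuning/test split of {len(ac_triples)} "
            f"AC triples found in {max_retries} attempts; colliding cores: "
            f"{sorted(colliding)}")

    test_ccr = [t for t in ccr_triples if t.core not in ft_cores]
    dropped = len(ccr_triples) - len(test_ccr)
    if dropped:
        log.info("class %s: excluded %d CCR pairs sharing cores with the "
                 "fine-tuning set", class_id, dropped)

    ac_cpds = _unique_compounds(test_ac)
    ccr_cpds = _unique_compounds(test_ccr)
    n_overlapping = len(set(ac_cpds) & set(ccr_cpds))
    all_cpds = {**ccr_cpds, **ac_cpds}
    sources = sorted((c for c in all_cpds.values() if c.pki <= SC_PKI_MAX),
                     key=lambda c: c.structure)
    ktcs = sorted((c for c in all_cpds.values() if c.pki > SC_PKI_MAX),
                  key=lambda c: c.structure)
    return TestPartition(class_id=class_id, finetune_triples=finetune,
                         test_ac_triples=test_ac, test_ccr_triples=test_ccr,
                         sources=sources, known_targets=ktcs,
                         n_overlapping=n_overlapping)


def sc_ktc_pairs(partition: TestPartition
                 ) -> list[tuple[CompoundRecord, CompoundRecord]]:
    """Test pairs whose weak member is an SC and potent member a KTC."""
    out = []
    for t in partition.test_triples:
        lo, hi = sorted((t.source, t.target), key=lambda c: (c.pki, c.structure))
        if lo.pki <= SC_PKI_MAX < hi.pki:
            out.append((lo, hi))
    return out


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def score_reproducibility(partition: TestPartition,
                          generations: dict[str, GenerationResult],
                          fraction: float = 1.0, arm: str = ""
                          ) -> EvaluationReport:
    """Score sampled candidates against the known target compounds.

    ``generations`` maps each SC structure to its sampled candidates. An
    SC-KTC pair counts as reproduced when the KTC's canonical structure
    occurs among the SC's valid candidates; unique KTCs are deduplicated
    across pairs and reproducibility is their percentage of the class's
    KTCs. Valid candidates matching no test compound are counted as
    novel (unique structures).
    """
    test_structures = {c.structure for c in partition.sources} | \
                      {c.structure for c in partition.known_targets}
    pairs = sc_ktc_pairs(partition)
    reproduced_ktcs: dict[str, CompoundRecord] = {}
    n_pairs = 0
    deltas: list[float] = []
    novel: set[str] = set()
    for sc_structure, gen in generations.items():
        novel |= {s for s in gen.valid_set if s not in test_structures}
    for sc, ktc in pairs:
        gen = generations.get(sc.structure)
        if gen is None:
            continue
        if ktc.structure in gen.valid_set:
            n_pairs += 1
            reproduced_ktcs[ktc.structure] = ktc
            deltas.append(ktc.pki - sc.pki)
    n_ktc_total = len(partition.known_targets)
    pct = 100.0 * len(reproduced_ktcs) / n_ktc_total if n_ktc_total else 0.0
    return EvaluationReport(
        class_id=partition.class_id, fraction=fraction, arm=arm,
        n_sc_ktc_pairs=n_pairs, n_unique_ktc=len(reproduced_ktcs),
        reproducibility_pct=pct, n_novel_candidates=len(novel),
        ktc_pki_values=[c.pki for c in reproduced_ktcs.values()],
        sc_ktc_delta_values=deltas)


# ----------------------------------------------------------------------
# Arm comparison
# ----------------------------------------------------------------------

def welch_ttest(a, b) -> SignificanceAnnotation:
    """Independent-samples t-test (Welch, unequal variances), two-sided."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per arm")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return SignificanceAnnotation(p_value=p, stars=stars_from_p(p))


def compare_arms(reports_a: list[EvaluationReport],
                 reports_b: list[EvaluationReport]
                 ) -> dict[tuple[str, float], dict[str, SignificanceAnnotation]]:
    """Per (class, fraction): t-tests of arm A vs arm B replicate runs.

    Three comparisons mirror the standard readouts: per-run
    reproducibility percentages, pooled potency values of reproduced
    KTCs, and pooled SC-KTC potency differences.
    """
    def index(reports):
        idx: dict[tuple[str, float], list[EvaluationReport]] = {}
        for r in reports:
            idx.setdefault((r.class_id, r.fraction), []).append(r)
        return idx

    ia, ib = index(reports_a), index(reports_b)
    out: dict[tuple[str, float], dict[str, SignificanceAnnotation]] = {}
    for key in sorted(set(ia) & set(ib)):
        ra, rb = ia[key], ib[key]
        if len(ra) < 2 or len(rb) < 2:
            raise ValueError(
                f"need >= 2 replicate runs per arm for {key}; "
                f"got {len(ra)} vs {len(rb)}")
        entry: dict[str, SignificanceAnnotation] = {
            "reproducibility": welch_ttest(
                [r.reproducibility_pct for r in ra],
                [r.reproducibility_pct for r in rb])}
        pki_a = [v for r in ra for v in r.ktc_pki_values]
        pki_b = [v for r in rb for v in r.ktc_pki_values]
        if len(pki_a) >= 2 and len(pki_b) >= 2:
            entry["ktc_pki"] = welch_ttest(pki_a, pki_b)
        d_a = [v for r in ra for v in r.sc_ktc_delta_values]
        d_b = [v for r in rb for v in r.sc_ktc_delta_values]
        if len(d_a) >= 2 and len(d_b) >= 2:
            entry["sc_ktc_delta"] = welch_ttest(d_a, d_b)
        out[key] = entry
    return out


# ----------------------------------------------------------------------
# Report I/O
# ----------------------------------------------------------------------

def write_reports(reports: list[EvaluationReport], out_dir: str | Path) -> Path:
    """TSV of per-run counts plus a JSON dump with the distributions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "reports.tsv"
    with open(tsv, "w") as fh:
        fh.write("class_id\tfraction\tarm\tsc_ktc_pairs\tunique_ktcs\t"
                 "reproducibility_pct\tnovel_candidates\n")
        for r in reports:
            fh.write(f"{r.class_id}\t{r.fraction:.2f}\t{r.arm}\t"
                     f"{r.n_sc_ktc_pairs}\t{r.n_unique_ktc}\t"
                     f"{r.reproducibility_pct:.1f}\t{r.n_novel_candidates}\n")
    (out_dir / "reports.json").write_text(json.dumps(
        [r.__dict__ for r in reports], indent=1))
    return tsv
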