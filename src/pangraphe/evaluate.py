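"""Scoring a pipeline run against simulator ground truth."""

from __future__ import annotations

from sklearn.metrics import adjusted_rand_score

from .paralogs import DUPLICATION
from .pipeline import PangenomeResult
from .simulate import EVENT_DUPLICATION, EVENT_FISSION, TruthTable


def family_ari(result: PangenomeResult, truth: TruthTable) -> float:
    """Adjusted Rand index between inferred and true family memberships,
    over every retained locus present in the truth table."""
    family_of = result.hierarchy.family_of()
    loci = sorted(l for l in family_of if l in truth.events)
    predicted = [family_of[l] for l in loci]
    actual = [truth.family_of(l) for l in loci]
    return float(adjusted_rand_score(actual, predicted))


def duplication_accuracy(result: PangenomeResult, truth: TruthTable) -> float:
    """Fraction of true (family, genome) duplication events for which the
    classifier reports the right number of extra copies — and no spurious
    duplication calls elsewhere count against it via the denominator."""
    genome_of = {l.locus_id: l.genome_id for l in result.retained}
    true_counts: dict[tuple[str, str], int] = {}
    for locus in truth.loci_with_event(EVENT_DUPLICATION):
        if locus not in genome_of:
            continue
        key = (truth.family_of(locus), genome_of[locus])
        true_counts[key] = true_counts.get(key, 0) + 1
    truth_family_of = {l: truth.family_of(l) for l in truth.events}
    pred_counts: dict[tuple[str, str], int] = {}
    for ann in result.paralog_annotations:
        if ann.classification != DUPLICATION:
            continue
        fam = truth_family_of.get(ann.locus_id)
        if fam is None:
            continue
        key = (fam, genome_of[ann.locus_id])
        pred_counts[key] = pred_counts.get(key, 0) + 1
    events = set(true_counts) | set(pred_counts)
    if not events:
        return 1.0
    correct = sum(1 for key in events
                  if true_counts.get(key) == pred_counts.get(key))
    return correct / len(events)


def fission_accuracy(result: PangenomeResult, truth: TruthTable) -> float:
    """Fraction of true fission events whose fragment set is recovered as
    exactly one reported fission group (spurious groups enter the
    denominator)."""
    true_groups: dict[str, set[str]] = {}
    for locus, (_, event, group) in truth.events.items():
        if event == EVENT_FISSION:
            true_groups.setdefault(group, set()).add(locus)
    pred_sets = [frozenset(g.fragment_loci) for g in result.fission_groups]
    true_sets = [frozenset(s) for s in true_groups.values()]
    if not true_sets and not pred_sets:
        return 1.0
    matched = sum(1 for s in true_sets if pred_sets.count(s) == 1)
    n_events = len(set(true_sets) | set(pred_sets))
    return matched / n_events if n_events else 1.0
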