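"""Scoring of pipeline output against a simulated cohort's planted truth.

Each scorer compares one stage's calls with the generator's truth tables
and returns plain sensitivity / FDR / accuracy numbers, so end-to-end
performance of the analysis on data with known ground truth can be
reported (and asserted) uniformly.
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from .synthetic import CohortSpec

__all__ = [
    "predicted_response",
    "score_switching",
    "score_response_classes",
    "score_spurious_filter",
    "score_assignment",
    "score_internal_calls",
    "score_derepression",
    "false_switch_rate",
]


def predicted_response(events: pd.DataFrame) -> pd.Series:
    """Gene-level main-TSS response class from the pair-level event table.

    Among timepoints where the alternative fired (main_response not null):
    'down' wins over 'up' wins over 'unchanged'; genes whose alternatives
    never fire get no prediction.
    """
    rows = events[events.main_response.notna()]

    def classify(group: pd.Series) -> Optional[str]:
        if (group == "down").any():
            return "down"
        if (group == "up").any():
            return "up"
        return "unchanged"

    return rows.groupby("gene_id").main_response.agg(classify)


def score_switching(spec: CohortSpec, events: pd.DataFrame) -> Dict[str, float]:
    """Gene-level switching sensitivity and FDR against planted truth."""
    called = set(events.loc[events.is_switch, "gene_id"])
    truth_switch = {g for g, t in spec.truth.items() if t.switch}
    tp = len(called & truth_switch)
    return {
        "sensitivity": tp / len(truth_switch) if truth_switch else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_true": len(truth_switch),
        "n_called": len(called),
    }


def score_response_classes(
    spec: CohortSpec, events: pd.DataFrame
) -> Dict[str, float]:
    """Per-class accuracy of the down/up/unchanged response call."""
    preds = predicted_response(events)
    out: Dict[str, float] = {}
    for label, want in (
        ("repressed", "down"),
        ("coactivated", "up"),
        ("neutral", "unchanged"),
    ):
        genes = [g for g, t in spec.truth.items() if t.label == label]
        if not genes:
            continue
        correct = sum(1 for g in genes if preds.get(g) == want)
        out[f"accuracy_{want}"] = correct / len(genes)
        out[f"n_{want}"] = len(genes)
    return out


def score_spurious_filter(
    spec: CohortSpec, spurious_calls: pd.DataFrame, clusters: pd.DataFrame
) -> Dict[str, float]:
    """Fraction of planted spurious promoters flagged, and false flags on
    genuine planted clusters."""
    planted_anchors = {
        (p.strand, p.anchor) for p in spec.plans if p.role == "spurious"
    }
    true_anchors = {
        (p.strand, p.anchor)
        for p in spec.plans
        if p.kind == "TSS" and p.role in ("main", "alternative", "internal")
    }
    merged = spurious_calls.merge(clusters, on="cluster_id")
    flagged = {
        (r.strand, r.apex) for r in merged[merged.spurious].itertuples()
    }
    detected = sum(1 for a in planted_anchors if a in flagged)
    false = sum(1 for a in true_anchors if a in flagged)
    return {
        "detected_fraction": detected / len(planted_anchors)
        if planted_anchors
        else float("nan"),
        "false_flags": false,
        "n_planted": len(planted_anchors),
    }


def score_assignment(spec: CohortSpec, result: Dict) -> Dict[str, float]:
    """Fraction of planted clusters assigned to the right gene/category."""
    assigned = {
        row.cluster_id: row
        for row in result["tables"]["assignments"].itertuples()
    }
    clusters = {
        c.cluster_id: c
        for c in result["kept_tss"] + result["tes_clusters"]
    }
    anchor_to_plan = {
        (p.strand, p.kind, p.anchor): p
        for p in spec.plans
        if p.gene_id and p.role in ("main", "alternative", "internal", "tes")
    }
    expected_cat = {
        "main": "upstream",
        "alternative": "upstream",
        "internal": "internal",
        "tes": "downstream",
    }
    total = correct = 0
    for cid, c in clusters.items():
        plan = anchor_to_plan.get((c.strand, c.kind, c.apex))
        if plan is None:
            continue
        total += 1
        row = assigned.get(cid)
        if (
            row is not None
            and row.gene_id == plan.gene_id
            and row.category == expected_cat[plan.role]
        ):
            correct += 1
    return {
        "recovery": correct / total if total else float("nan"),
        "n_planted_found": total,
    }


def score_internal_calls(
    spec: CohortSpec, internal_calls: pd.DataFrame
) -> Dict[str, float]:
    """Relaxed/stringent internal-TSS recovery vs planted truth."""
    by_gene = internal_calls.groupby("gene_id")[["relaxed", "stringent"]].any()
    out: Dict[str, float] = {}
    for field in ("internal_relaxed", "internal_stringent"):
        genes = [g for g, t in spec.truth.items() if getattr(t, field)]
        col = field.replace("internal_", "")
        hits = sum(
            1 for g in genes if g in by_gene.index and bool(by_gene.loc[g, col])
        )
        out[f"{col}_recovery"] = hits / len(genes) if genes else float("nan")
    subset_ok = not (internal_calls.stringent & ~internal_calls.relaxed).any()
    out["stringent_subset_of_relaxed"] = float(subset_ok)
    return out


def false_switch_rate(events: pd.DataFrame) -> float:
    """Fraction of evaluated genes with any switch call (null datasets)."""
    if events.empty:
        return 0.0
    per_gene = events.groupby("gene_id").is_switch.any()
    return float(per_gene.mean())


def score_derepression(
    derepression: pd.DataFrame, truth: pd.DataFrame
) -> Dict[str, float]:
    planted = set(truth.loc[truth.derepressed, "gene_id"])
    called = set(derepression.loc[derepression.derepressed, "gene_id"])
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_planted": len(planted),
        "n_called": len(called),
    }
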