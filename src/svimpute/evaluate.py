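"""Imputation performance metrics.

PPV (positive predictive value) = correct calls / (correct + incorrect)
among non-missing imputed genotypes; "correct" is an exact diploid dosage
match.  Recall = calls passing the posterior cut-off / total variants in
the reference panel, so strategies that exclude evidence-less SVs pay a
recall penalty against the full panel denominator.  SV metrics are
additionally stratified into length bins.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sites import reciprocal_overlap_match
from .types import (
    SNV,
    SV_CLASSES,
    ImputedRecord,
    TrueGenotypes,
    Variant,
)

#: SV length bins in bp, left-closed right-open; the last bin is closed.
LENGTH_BINS: tuple[tuple[int, int], ...] = (
    (100, 500),
    (500, 1000),
    (1000, 2000),
    (2000, 5000),
    (5000, 10_000),
    (10_000, 2_000_000),
)


def length_bin(length: int) -> str:
    """Label of the SV length bin containing ``length``."""
    for lo, hi in LENGTH_BINS:
        if lo <= length < hi or (hi == LENGTH_BINS[-1][1] and length == hi):
            return f"{lo}-{hi}"
    raise ValueError(f"length {length} outside the binning range [100, 2000000]")


def apply_pp_cutoff(
    records: Sequence[ImputedRecord], cutoff: float
) -> list[ImputedRecord]:
    """Flag records with PP below the cut-off as missing ('./.')."""
    return [
        replace(rec, missing=True) if rec.pp < cutoff else replace(rec, missing=False)
        for rec in records
    ]


def ppv(records: Sequence[ImputedRecord], truth: Mapping[str, int]) -> Optional[float]:
    """Fraction of non-missing calls whose dosage matches truth exactly.

    Missing calls are excluded from numerator and denominator; with zero
    non-missing calls the PPV is undefined and None is returned.
    """
    correct = incorrect = 0
    for rec in records:
        if rec.missing:
            continue
        if rec.variant.id not in truth:
            raise ValueError(f"no truth dosage for {rec.variant.id}")
        if rec.call == truth[rec.variant.id]:
            correct += 1
        else:
            incorrect += 1
    if correct + incorrect == 0:
        return None
    return correct / (correct + incorrect)


def recall(n_passing_calls: int, n_total_panel: int) -> float:
    """Proportion of panel variants with a passing imputed call."""
    if n_total_panel <= 0:
        raise ValueError("n_total_panel must be positive")
    return n_passing_calls / n_total_panel


def curation_discard_rate(n_raw: int, n_retained: int) -> float:
    """Fraction of raw calls discarded by curation, (raw - kept) / raw."""
    if n_raw <= 0 or not 0 <= n_retained <= n_raw:
        raise ValueError("need 0 <= n_retained <= n_raw with n_raw > 0")
    return (n_raw - n_retained) / n_raw


def confusion_matrix(
    records: Sequence[ImputedRecord], truth: Mapping[str, int]
) -> np.ndarray:
    """3x3 matrix of true (rows) vs imputed (columns) dosages, non-missing."""
    mat = np.zeros((3, 3), dtype=int)
    for rec in records:
        if not rec.missing:
            mat[truth[rec.variant.id], rec.call] += 1
    return mat


def match_truth_to_panel(
    truth_variants: Sequence[Variant],
    panel_variants: Sequence[Variant],
    overlap_threshold: float = 0.90,
) -> dict[str, str]:
    """Map truth variant ids to panel variant ids.

    SNVs match on exact chromosome/position; SVs on same-class reciprocal
    overlap at the threshold.  Used to restrict out-panel evaluation to
    the variants shared with the panel.
    """
    mapping: dict[str, str] = {}
    panel_snvs = {(v.chrom, v.pos): v.id for v in panel_variants if v.var_class == SNV}
    panel_svs = [v for v in panel_variants if v.is_sv]
    for t in truth_variants:
        if t.var_class == SNV:
            hit = panel_snvs.get((t.chrom, t.pos))
            if hit is not None:
                mapping[t.id] = hit
        else:
            for p in panel_svs:
                if reciprocal_overlap_match(t, p, overlap_threshold):
                    mapping[t.id] = p.id
                    break
    return mapping


def _stratum_row(
    records: list[ImputedRecord],
    truth: Mapping[str, int],
    n_total: int,
    meta: dict,
) -> dict:
    n_correct = sum(
        1 for r in records if not r.missing and r.call == truth[r.variant.id]
    )
    n_incorrect = sum(
        1 for r in records if not r.missing and r.call != truth[r.variant.id]
    )
    n_missing = sum(1 for r in records if r.missing)
    p = ppv(records, truth)
    return {
        **meta,
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "n_missing": n_missing,
        "n_total_panel": n_total,
        "ppv": math.nan if p is None else p,
        "recall": recall(n_correct + n_incorrect, n_total) if n_total else math.nan,
    }


def evaluate(
    records: Sequence[ImputedRecord],
    truth: TrueGenotypes,
    panel_variants: Sequence[Variant],
    pp_cutoffs: Sequence[float] = (0.60, 0.75, 0.90),
    sample: str = "",
    depth: float = math.nan,
    strategy: str = "",
) -> pd.DataFrame:
    """Long-format PPV/recall table per class, cut-off and SV length bin.

    Truth is restricted to panel variants (exact match for SNVs,
    reciprocal overlap for SVs); private variants never enter a
    denominator.  Recall denominators are full panel counts per stratum.
    """
    id_map = match_truth_to_panel(truth.variants, panel_variants)
    truth_dosage = {
        id_map[v.id]: truth.dosage[v.id] for v in truth.variants if v.id in id_map
    }
    panel_by_id = {v.id: v for v in panel_variants}
    unknown = [r.variant.id for r in records if r.variant.id not in panel_by_id]
    if unknown:
        raise ValueError(f"imputed records not in the panel: {unknown[:5]}")
    missing_truth = [
        r.variant.id for r in records if r.variant.id not in truth_dosage
    ]
    if missing_truth:
        raise ValueError(f"no truth for imputed records: {missing_truth[:5]}")

    class_totals = {
        c: sum(1 for v in panel_variants if v.var_class == c)
        for c in (SNV, *SV_CLASSES)
    }
    bin_totals = {
        (c, length_bin(v.length)): 0 for c in SV_CLASSES for v in panel_variants
        if v.is_sv
    }
    for v in panel_variants:
        if v.is_sv:
            bin_totals[(v.var_class, length_bin(v.length))] = (
                bin_totals.get((v.var_class, length_bin(v.length)), 0) + 1
            )

    rows = []
    for cutoff in pp_cutoffs:
        filtered = apply_pp_cutoff(records, cutoff)
        for cls in (SNV, *SV_CLASSES):
            if class_totals[cls] == 0:
                continue
            cls_recs = [r for r in filtered if r.variant.var_class == cls]
            meta = {
                "sample": sample, "depth": depth, "strategy": strategy,
                "var_class": cls, "pp_cutoff": cutoff, "length_bin": "all",
            }
            rows.append(_stratum_row(cls_recs, truth_dosage, class_totals[cls], meta))
            if cls in SV_CLASSES:
                by_bin: dict[str, list[ImputedRecord]] = {}
                for r in cls_recs:
                    by_bin.setdefault(length_bin(r.variant.length), []).append(r)
                for (c, b), total in sorted(bin_totals.items()):
                    if c != cls:
                        continue
                    rows.append(
                        _stratum_row(
                            by_bin.get(b, []), truth_dosage, total,
                            {**meta, "length_bin": b},
                        )
                    )
    return pd.DataFrame(rows)
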