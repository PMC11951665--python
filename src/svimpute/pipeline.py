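"""Experimental-design orchestration: leave-one-out panels, the two base
imputation strategies per depth, and the logical / non-logical merge.

The two base strategies per target and depth are

* ``ld_only`` — SVs are imputed purely from LD with flanking SNVs; every
  panel SV receives a call.
* ``gl_supplemented`` — SV genotype likelihoods (phred-scaled, as an SV
  genotyper would emit them) enter the model; SVs whose evidence dropped
  out at low coverage are absent from the output.

Merging recombines the two outputs per SV: "logical" keeps whichever
record has the higher posterior support (PP), "non-logical" always keeps
the GL-supplemented record; SVs only the LD run covers are appended
either way, so both merges cover the union of the two SV sets.
"""

from __future__ import annotations

import numpy as np

from .config import (
    DEFAULT_BUFFER,
    DEFAULT_WINDOW,
    GL_SUPPLEMENTED,
    IN_PANEL,
    LD_ONLY,
    MERGED_LOGICAL,
    MERGED_NON_LOGICAL,
    HMMParams,
    RunSpec,
    SimulationConfig,
)
from .hmm import impute_sample
from .simulate import simulate_snv_evidence, simulate_sv_evidence
from .sites import chunk_genome, merge_likelihood_sets
from .types import HaplotypePanel, ImputedRecord, SiteLikelihoods, TrueGenotypes


def leave_one_out(panel: HaplotypePanel, sample: str) -> HaplotypePanel:
    """Panel with both haplotypes of ``sample`` removed.

    The variant list is unchanged: sites that become monomorphic in the
    reduced panel are retained.
    """
    r0, r1 = panel.sample_rows(sample)  # raises for unknown sample
    keep = [i for i in range(panel.n_haplotypes) if i not in (r0, r1)]
    return HaplotypePanel(
        panel.haplotypes[keep],
        [s for s in panel.samples if s != sample],
        list(panel.variants),
    )


def simulate_evidence(
    truth: TrueGenotypes,
    depth: float,
    sim: SimulationConfig,
    seed: int,
) -> dict[str, SiteLikelihoods]:
    """Merged SNV GL + SV PL evidence for one target at one depth.

    SNV read draws are keyed by (seed, depth) and therefore independent
    across depths; the SV dropout draw is keyed by seed only, so the SVs
    with evidence at a lower depth are a subset of those at a higher depth
    under the same seed (mirroring down-sampling of one sequencing run).
    """
    snv_ev = simulate_snv_evidence(
        truth, depth, sim.base_error, seed=int(seed) * 1000 + int(round(depth * 10))
    )
    sv_ev = simulate_sv_evidence(truth, depth, sim, seed=seed)
    return merge_likelihood_sets(snv_ev, sv_ev)


def run_strategy(
    spec: RunSpec,
    panel: HaplotypePanel,
    truth: TrueGenotypes,
    sim: SimulationConfig,
    params: HMMParams = HMMParams(),
    window: int = DEFAULT_WINDOW,
    buffer: int = DEFAULT_BUFFER,
) -> list[ImputedRecord]:
    """Simulate evidence at ``spec.depth`` and impute under ``spec.strategy``.

    For merged strategies the two base runs are executed and merged.
    In-panel targets are imputed against the leave-one-out panel.
    """
    if spec.strategy in (MERGED_LOGICAL, MERGED_NON_LOGICAL):
        base = {
            mode: run_strategy(
                RunSpec(spec.sample, spec.depth, mode, spec.pp_cutoffs, spec.seed),
                panel, truth, sim, params, window, buffer,
            )
            for mode in (LD_ONLY, GL_SUPPLEMENTED)
        }
        mode = "logical" if spec.strategy == MERGED_LOGICAL else "non_logical"
        return merge_strategies(base[LD_ONLY], base[GL_SUPPLEMENTED], mode)

    evidence = simulate_evidence(truth, spec.depth, sim, spec.seed)
    run_panel = (
        leave_one_out(panel, truth.sample) if truth.mode == IN_PANEL else panel
    )
    chunks = chunk_genome(sim.chrom_length, sim.chrom, window, buffer)
    return impute_sample(run_panel, evidence, chunks, params, spec.strategy)


def merge_strategies(
    run_ld: list[ImputedRecord],
    run_gl: list[ImputedRecord],
    mode: str,
) -> list[ImputedRecord]:
    """Combine the LD-only and GL-supplemented outputs of one target.

    SNV records are taken from the LD-only run unchanged (they are
    identical between runs).  For each SV present in both runs, "logical"
    keeps the record with the higher PP (ties go to the GL-supplemented
    record), "non_logical" keeps the GL-supplemented record; SVs present
    only in the LD-only run are appended.  Posterior cut-offs are applied
    downstream, after merging.
    """
    if mode not in ("logical", "non_logical"):
        raise ValueError("mode must be 'logical' or 'non_logical'")
    ld_ids = {r.variant.id for r in run_ld}
    gl_by_id = {r.variant.id: r for r in run_gl}
    snv_ids_ld = {r.variant.id for r in run_ld if not r.variant.is_sv}
    snv_ids_gl = {r.variant.id for r in run_gl if not r.variant.is_sv}
    extra = set(gl_by_id) - ld_ids
    if snv_ids_ld != snv_ids_gl or extra:
        raise ValueError(
            "runs disagree on variant identity: "
            f"{sorted((snv_ids_ld ^ snv_ids_gl) | extra)[:5]}"
        )
    merged: list[ImputedRecord] = []
    for rec in run_ld:
        if not rec.variant.is_sv:
            merged.append(rec)
            continue
        gl_rec = gl_by_id.get(rec.variant.id)
        if gl_rec is None:
            merged.append(rec)  # completion with the LD-only call
        elif mode == "non_logical":
            merged.append(gl_rec)
        else:
            merged.append(gl_rec if gl_rec.pp >= rec.pp else rec)
    merged.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.variant.id))
    return merged
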