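"""End-to-end orchestration of the pipeline stages.

Chains simulate -> group ICA -> component selection -> dual regression ->
classification / netmat statistics, passing in-memory objects between
stages and optionally persisting each stage's outputs.  The CLI is a thin
wrapper over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dual_regression as dr
from . import group_ica as gi
from . import netmats as nm
from . import selection as sel
from .cnn import ArchitectureSpec, FoldResult, TrainConfig, run_cross_validation
from .io_core import BrainMask, StudyConfig, SubjectTable, VolumeSeries, compute_mask
from .synthetic import CohortGroundTruth, EffectSpec, SourceSpec, generate_cohort

__all__ = ["PipelineState", "run_simulate", "run_gica", "run_select",
           "run_dualreg", "run_train", "run_netstats", "run_all"]


@dataclass
class PipelineState:
    """Everything produced so far in one run."""

    config: StudyConfig
    table: SubjectTable | None = None
    truth: CohortGroundTruth | None = None
    series: list[VolumeSeries] = field(default_factory=list)
    mask: BrainMask | None = None
    components: gi.ComponentSet | None = None
    report: sel.SelectionReport | None = None
    subject_tcs: list[np.ndarray] = field(default_factory=list)   # T x K, all components
    stacks: np.ndarray | None = None                              # (N, C, H, W, D)
    channel_names: list[str] = field(default_factory=list)
    fold_results: list[FoldResult] = field(default_factory=list)
    mean_metrics: dict = field(default_factory=dict)
    znetmats: list[np.ndarray] = field(default_factory=list)
    edge_comparison: nm.EdgeComparison | None = None


def run_simulate(config: StudyConfig, n_case: int, n_control: int,
                 effect: EffectSpec | None = None,
                 spec: SourceSpec | None = None,
                 out_dir: str | Path | None = None,
                 T: int | None = None) -> PipelineState:
    spec = spec or SourceSpec(K=config.n_selected_networks)
    effect = effect or EffectSpec.strong(K=spec.K)
    kwargs = {} if T is None else {"T": T}
    table, truth, series = generate_cohort(
        n_case, n_control, spec, effect, seed=config.seed,
        out_dir=out_dir or ".", write_files=out_dir is not None, **kwargs)
    state = PipelineState(config=config, table=table, truth=truth, series=series)
    return state


def run_gica(state: PipelineState, K: int | None = None,
             threshold: bool = True) -> PipelineState:
    K = K or state.config.n_ica_components
    state.mask = compute_mask(state.series)
    concat, scales = gi.temporal_concat(state.series, state.mask,
                                        return_scales=True)
    cset = gi.ica_decompose(concat, K=K, seed=state.config.seed,
                            voxel_scales=scales)
    gi.z_transform_maps(cset)
    if threshold:
        fits, masks = [], []
        for k in range(cset.K):
            fit = gi.fit_gauss_gamma_mixture(cset.zmaps[k])
            fits.append(fit)
            masks.append(gi.threshold_map(cset.zmaps[k], fit))
        cset.mixture_fits = fits
        cset.threshold_masks = np.stack(masks)
    state.components = cset
    return state


def run_select(state: PipelineState,
               references: dict[str, np.ndarray] | None = None,
               r_min: float = sel.DEFAULT_R_MIN) -> PipelineState:
    if references is None:
        # default references: the generator's own ground-truth maps on the mask
        truth = state.truth
        if truth is None:
            raise ValueError("no references given and no synthetic ground truth")
        flat = truth.maps_control[:, state.mask.mask.ravel()]
        references = {name: flat[k] for k, name in enumerate(truth.network_names)}
    tr = state.series[0].tr_seconds
    state.report = sel.select_components(state.components, tr, references,
                                         r_min=r_min)
    return state


def run_dualreg(state: PipelineState, des_norm: bool = True,
                pad_shape: tuple[int, int, int] | None = None) -> PipelineState:
    cset, report, mask = state.components, state.report, state.mask
    templates = cset.maps
    pad_shape = pad_shape or tuple(
        max(p, s) for p, s in zip(state.config.grid_pad_shape, mask.mask.shape))
    if any(p < s for p, s in zip(pad_shape, mask.mask.shape)):
        pad_shape = mask.mask.shape
    stacks, tcs_list = [], []
    for series in state.series:
        stc, maps = dr.dual_regress_subject(templates, series, mask,
                                            des_norm=des_norm)
        tcs_list.append(stc.tcs)
        stack = dr.assemble_subject_stack(
            maps, report.selected, mask, pad_shape,
            channel_names=report.selected_names, subject_id=series.subject_id)
        stacks.append(stack.maps)
    state.subject_tcs = tcs_list
    state.stacks = np.stack(stacks).astype(np.float32)
    state.channel_names = list(report.selected_names)
    return state


def run_train(state: PipelineState, mode: str = "mcse",
              k: int | None = None) -> PipelineState:
    cfg = state.config
    tconf = TrainConfig(lr=cfg.lr, lr_decay_factor=cfg.lr_decay_factor,
                        lr_patience_epochs=cfg.lr_patience_epochs,
                        batch_size=cfg.batch_size, l2_weight=cfg.l2_weight,
                        max_epochs=cfg.max_epochs,
                        early_stop_patience=cfg.early_stop_patience,
                        seed=cfg.seed)
    aspec = ArchitectureSpec(in_channels=state.stacks.shape[1],
                             width_multiplier=cfg.width_multiplier,
                             se_reduction=cfg.se_reduction,
                             leaky_slope=cfg.leaky_slope, dropout=cfg.dropout)
    labels = state.table.labels
    state.fold_results, state.mean_metrics = run_cross_validation(
        state.stacks, labels, state.channel_names, tconf, aspec, mode=mode,
        k=k or cfg.n_folds)
    return state


def run_netstats(state: PipelineState) -> PipelineState:
    """Ridge partial correlation on the selected components' stage-1 time
    courses (estimated jointly with the artifact regressors), Fisher z,
    permutation GLM."""
    cfg = state.config
    selected = state.report.selected
    znet = []
    for sid, tcs in zip(state.table.subject_ids, state.subject_tcs):
        net = nm.partial_corr_ridge(tcs[:, selected], rho=cfg.rho,
                                    subject_id=sid)
        znet.append(nm.fisher_z(net))
    state.znetmats = znet
    state.edge_comparison = nm.permutation_group_test(
        znet, state.table.labels, n_perm=cfg.n_perm, seed=cfg.seed,
        alpha=cfg.alpha)
    return state


def run_all(config: StudyConfig, n_case: int, n_control: int,
            effect: EffectSpec | None = None, spec: SourceSpec | None = None,
            mode: str = "mcse", T: int | None = None,
            n_ica: int | None = None, k: int | None = None,
            out_dir: str | Path | None = None) -> PipelineState:
    state = run_simulate(config, n_case, n_control, effect=effect, spec=spec,
                         out_dir=out_dir, T=T)
    run_gica(state, K=n_ica, threshold=False)
    run_select(state)
    run_dualreg(state)
    run_train(state, mode=mode, k=k)
    run_netstats(state)
    return state
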