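"""Two-phase uncertainty-based sample-selection training.

Phase 1 trains the windowed network on every training spectrum, then scores
each *training* spectrum's Monte Carlo Dropout variance.  A refined training
set keeps all control spectra and, per disease donor, only the
lowest-variance spectra — never fewer than max(1, ceil(retention_floor * n))
per donor.  Phase 2 re-initializes the network from fresh random weights
(warm-starting tends to keep the optimizer in the minimum shaped by the
noisy phase-1 set) and retrains on the refined set for the full epoch
budget.  Test folds are never masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mc_dropout import UncertaintyReport, mc_predict, rank_by_uncertainty
from .spectral_data import DonorRecord, SpectrumSet
from .windowed_net import NetConfig, TrainedNet, build_net, train

#: phase-2 seed = phase-1 seed + this fixed offset (fresh, decorrelated init)
PHASE2_SEED_OFFSET = 104729


@dataclass
class SelectionPolicy:
    """How "high uncertainty" maps to exclusion.

    ``lowest_fraction`` keeps the ceil(keep_fraction * n) lowest-variance
    spectra per disease donor; ``below_threshold`` keeps spectra with
    Var(y) <= threshold.  Either way at least max(1, ceil(retention_floor*n))
    spectra per donor survive.
    """

    retention_floor: float = 0.20
    keep_rule: str = "lowest_fraction"
    keep_fraction: float = 0.40
    threshold: float | None = None

    def validate(self) -> None:
        if not 0.0 < self.retention_floor <= 1.0:
            raise ValueError("retention_floor must be in (0, 1]")
        if self.keep_rule not in ("lowest_fraction", "below_threshold"):
            raise ValueError(f"unknown keep_rule {self.keep_rule!r}")
        if self.keep_rule == "lowest_fraction" and not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.keep_rule == "below_threshold" and self.threshold is None:
            raise ValueError("below_threshold rule requires a threshold")


@dataclass
class SelectionMask:
    keep: set[str]
    dropped: dict[str, float]  # spectrum_id -> Var(y) at exclusion time

    def __post_init__(self):
        overlap = self.keep & set(self.dropped)
        if overlap:
            raise ValueError(f"spectra both kept and dropped: {sorted(overlap)[:5]}")


def select_training_spectra(
    reports: list[UncertaintyReport],
    donors: list[DonorRecord],
    donor_of: dict[str, str],
    policy: SelectionPolicy | None = None,
) -> SelectionMask:
    """Build the phase-2 keep/drop mask from training-set uncertainty reports.

    Every control spectrum is kept.  Disease donors keep their
    lowest-variance spectra per the policy, with the per-donor floor.
    """
    policy = policy or SelectionPolicy()
    policy.validate()
    label_of = {d.donor_id: d.label for d in donors}
    for sid, donor in donor_of.items():
        if donor not in label_of:
            raise KeyError(f"spectrum {sid!r} maps to unknown donor {donor!r}")
    by_id = {r.spectrum_id: r for r in reports}
    ranked = rank_by_uncertainty(reports, donor_of)

    keep: set[str] = set()
    dropped: dict[str, float] = {}
    for donor, ordered in ranked.items():
        n = len(ordered)
        if n == 0:
            raise ValueError(f"donor {donor!r} has no spectra")
        if label_of[donor] == "control":
            keep.update(ordered)
            continue
        floor = max(1, math.ceil(policy.retention_floor * n))
        if policy.keep_rule == "lowest_fraction":
            n_keep = max(floor, math.ceil(policy.keep_fraction * n))
        else:
            n_keep = max(
                floor, sum(1 for s in ordered if by_id[s].var_y <= policy.threshold)
            )
        keep.update(ordered[:n_keep])
        for s in ordered[n_keep:]:
            dropped[s] = by_id[s].var_y
    return SelectionMask(keep=keep, dropped=dropped)


@dataclass
class TwoPhaseResult:
    phase2_net: TrainedNet
    mask: SelectionMask
    phase1_net: TrainedNet
    reports: list[UncertaintyReport]


def two_phase_train(
    train_set: SpectrumSet,
    net_config: NetConfig,
    T: int = 100,
    policy: SelectionPolicy | None = None,
    mcd_seed: int | None = None,
) -> TwoPhaseResult:
    """Run the full two-phase workflow on one training fold.

    Phase 1: train on all training spectra (net_config.seed); score MCD
    variance of every training spectrum (T passes).  Phase 2: fresh random
    initialization (seed + PHASE2_SEED_OFFSET, never warm-started) trained on
    the masked set for the same epoch budget.
    """
    policy = policy or SelectionPolicy()
    X = train_set.intensities
    y = train_set.labels().astype(float)
    n = X.shape[1]

    phase1 = train(build_net(net_config, n), X, y, net_config)
    reports = mc_predict(
        phase1,
        train_set,
        T=T,
        seed=net_config.seed if mcd_seed is None else mcd_seed,
    )
    mask = select_training_spectra(reports, train_set.donors, train_set.donor_of, policy)

    kept_ids = [s for s in train_set.spectrum_ids if s in mask.keep]
    refined = train_set.subset_spectra(kept_ids)
    y2 = refined.labels().astype(float)
    assert set(np.unique(y2)) == {0, 1}, "mask invariants guarantee both classes"

    cfg2 = NetConfig(**{**net_config.__dict__, "seed": net_config.seed + PHASE2_SEED_OFFSET})
    phase2 = train(build_net(cfg2, n), refined.intensities, y2, cfg2)
    return TwoPhaseResult(phase2_net=phase2, mask=mask, phase1_net=phase1, reports=reports)
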