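"""Synthetic-panel self-checks: parameter recovery and neutral calibration.

These helpers run the generator and the scan together and report how well
the three-criterion classifier recovers the generator's ground truth --
the package's internal benchmark of scan performance under the emulated
wild/landrace study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from domesticscan import popstats, selscan
from domesticscan.synthpop import SimulationConfig, simulate_gene


@dataclass
class RecoveryResult:
    """Gene-level call rates against simulation ground truth."""

    sensitivity_selected: float       # call rate on truly selected candidates
    call_rate_unselected: float       # call rate on unselected candidates
    false_call_rate_neutral: float    # call rate on neutral loci
    baseline: selscan.NeutralBaseline
    mean_wild_theta_pi: float
    mean_neutral_fst: float
    n_snps_total: int


def parameter_recovery(config: SimulationConfig) -> RecoveryResult:
    """Simulate a panel in memory, run the scan, score calls against truth.

    Candidate genes are split into selected and unselected halves per
    ``config.frac_selected``; neutral genes calibrate the RoD baseline
    exactly as in the disk pipeline.
    """
    rng = np.random.default_rng(config.rng_seed)
    wild = config.sample_ids[:config.n_wild]
    land = config.sample_ids[config.n_wild:]
    n_selected = int(round(config.frac_selected * config.n_candidate_genes))

    plan = ([("sel", True)] * n_selected
            + [("uns", False)] * (config.n_candidate_genes - n_selected)
            + [("neu", False)] * config.n_neutral_genes)
    matrices, kinds = [], []
    for i, (kind, is_sel) in enumerate(plan):
        matrices.append(simulate_gene(config, is_sel, rng, gene_id=f"{kind}{i:04d}"))
        kinds.append(kind)

    neutral_rods = []
    wild_pis, neutral_fsts = [], []
    for m, kind in zip(matrices, kinds):
        if kind != "neu":
            continue
        gs = popstats.gene_stats(m, wild, land)
        neutral_rods.append(gs.rod)
        wild_pis.append(gs.theta_pi_by_group[popstats.WILD])
        neutral_fsts.append(gs.fst)
    finite = np.array([r for r in neutral_rods if math.isfinite(r)])
    baseline = selscan.NeutralBaseline(
        mean_rod=float(finite.mean()),
        n_loci_used=len(finite),
        n_loci_excluded_nonfinite=len(neutral_rods) - len(finite),
    )

    called = {"sel": [], "uns": [], "neu": []}
    n_snps = 0
    for m, kind in zip(matrices, kinds):
        sites = popstats.per_site_stats(m, wild, land)
        n_snps += len(sites)
        flagged = selscan.flag_selected_snps(sites, baseline)
        called[kind].append(bool(flagged["selected"].any()))

    return RecoveryResult(
        sensitivity_selected=float(np.mean(called["sel"])) if called["sel"] else math.nan,
        call_rate_unselected=float(np.mean(called["uns"])) if called["uns"] else math.nan,
        false_call_rate_neutral=float(np.mean(called["neu"])),
        baseline=baseline,
        mean_wild_theta_pi=float(np.mean(wild_pis)),
        mean_neutral_fst=float(np.nanmean(neutral_fsts)),
        n_snps_total=n_snps,
    )


@dataclass
class CalibrationResult:
    """Wild-group summary statistics over neutral replicate genes."""

    mean_tajima_d: float
    se_tajima_d: float
    mean_segregating_sites: float
    mean_pooled_segregating_sites: float
    mean_theta_pi: float
    n_replicates: int


def neutral_calibration(config: SimulationConfig, n_replicates: int = 200) -> CalibrationResult:
    """Wild-group Tajima's D, S and theta-pi over neutral replicates.

    The wild population is panmictic at constant size for the entire
    history, so its expectations follow the standard neutral coalescent:
    E[S] = a1(n_wild) * theta * L and E[theta-pi] = theta.
    """
    rng = np.random.default_rng(config.rng_seed)
    wild = config.sample_ids[:config.n_wild]
    d_vals, s_vals, s_pool, pi_vals = [], [], [], []
    for _ in range(n_replicates):
        m = simulate_gene(config, False, rng)
        d = popstats.tajima_d(m, wild)
        if not math.isnan(d):
            d_vals.append(d)
        s_vals.append(popstats.segregating_sites(m, wild))
        s_pool.append(m.n_sites)
        pi_vals.append(popstats.theta_pi(m, wild))
    d_arr = np.array(d_vals)
    return CalibrationResult(
        mean_tajima_d=float(d_arr.mean()),
        se_tajima_d=float(d_arr.std(ddof=1) / math.sqrt(len(d_arr))),
        mean_segregating_sites=float(np.mean(s_vals)),
        mean_pooled_segregating_sites=float(np.mean(s_pool)),
        mean_theta_pi=float(np.nanmean(pi_vals)),
        n_replicates=n_replicates,
    )
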