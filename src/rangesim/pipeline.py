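"""Experiment orchestration: scenario x replicate runs, sampling, aggregation.

This module wires the landscape, engine, genetics and statistics together
into the full experimental design: for each contraction scenario, replicate
populations are burned in, contracted in four discrete events 100 timesteps
apart (~88% total range loss), and followed for 400 timesteps after the
final event.  Sampling follows the analysis scheme:

* 100 random individuals 50 timesteps after each contraction event, plus a
  pre-contraction baseline 50 timesteps before the first event and a final
  sample 400 timesteps after the last event;
* 50 individuals from each named region of the remnant range at the final
  timestep, compared against an "ancient" pre-contraction group;
* 50-individual pedigree-relatedness (F_r) samples on a fixed cadence;
* 4 random individuals alive 100 timesteps after the final contraction,
  whose ancestors' locations and genomic contributions are reported at two
  time slices (50 timesteps before the first event and 50 after the last).

Diversity declines are summarised as mean individual heterozygosity relative
to the same replicate's own pre-contraction mean; region groups additionally
get group pi, pairwise divergence pi12 and F_ST.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import popgen_stats as pg
from . import simcore
from .genetics import ancestry_contributions
from .landscape import ContractionSchedule, build_grid, make_schedule
from .simcore import SampleGroup, SamplingPlan, SimParams, SimResult

__all__ = [
    "region_groups_for",
    "build_sampling_plan",
    "run_replicate",
    "run_experiment",
    "ExperimentResult",
    "diversity_timecourse",
    "decline_summary",
    "ancestry_cloud",
    "fragmentation_min_fst",
    "ibd_correlation",
]

log = logging.getLogger(__name__)

PRE_LABEL = "pre"
FINAL_LABEL = "final"


# ---------------------------------------------------------------------------
# region groups


def region_groups_for(scenario: str, nx: int = 20, ny: int = 20) -> dict:
    """Named sampling rectangles (x0, y0, x1, y1) inside the remnant range.

    Shrinkage: four corner blocks plus a central block of the remnant
    rectangle.  Amputation: four equal segments along the long axis of the
    remnant strip.  Fragmentation: the four remnant corner patches (no
    central group exists post-contraction).  The no-contraction control and
    the random variant use the four quadrants of the full range.
    """
    if scenario in ("none", "random_fragmentation"):
        hx, hy = nx / 2.0, ny / 2.0
        return {
            "topleft": (0.0, hy, hx, float(ny)),
            "topright": (hx, hy, float(nx), float(ny)),
            "bottomleft": (0.0, 0.0, hx, hy),
            "bottomright": (hx, 0.0, float(nx), hy),
        }
    if scenario == "fragmentation":
        from .landscape import _fragmentation_patches

        out = {}
        for name, patch in _fragmentation_patches(nx, ny).items():
            xs = [c[0] for c in patch]
            ys = [c[1] for c in patch]
            out[name] = (float(min(xs)), float(min(ys)), float(max(xs) + 1), float(max(ys) + 1))
        return out
    sched = make_schedule(scenario, nx, ny)
    remnant = sched.remnant_cells()
    if scenario == "shrinkage":
        xs = [c[0] for c in remnant]
        ys = [c[1] for c in remnant]
        x0, x1 = min(xs), max(xs) + 1.0
        y0, y1 = min(ys), max(ys) + 1.0
        w, h = x1 - x0, y1 - y0
        xm = (x0 + x1) / 2.0
        return {
            "topleft": (x0, y1 - h / 3, xm, y1),
            "topright": (xm, y1 - h / 3, x1, y1),
            "bottomleft": (x0, y0, xm, y0 + h / 3),
            "bottomright": (xm, y0, x1, y0 + h / 3),
            "center": (x0 + w / 8, y0 + h / 3, x1 - w / 8, y1 - h / 3),
        }
    if scenario == "amputation":
        # rows that survive in full, segmented along x
        full_rows = [
            iy for iy in range(ny) if all((ix, iy) in remnant for ix in range(nx))
        ]
        y0, y1 = float(min(full_rows)), float(max(full_rows) + 1)
        seg = nx / 4.0
        names = ["left", "leftmiddle", "rightmiddle", "right"]
        return {nm: (k * seg, y0, (k + 1) * seg, y1) for k, nm in enumerate(names)}
    raise ValueError(f"unknown scenario {scenario!r}")


def build_sampling_plan(params: SimParams, schedule: ContractionSchedule) -> SamplingPlan:
    """The default sampling plan for one scenario run (see module docstring)."""
    first = schedule.first_event_time
    first = params.burn_in if first is None else first
    final = schedule.final_event_time
    final = first if final is None else final
    inject = first - params.genetics_lead
    if inject < 1:
        raise ValueError(
            f"genetics_lead {params.genetics_lead} does not fit before the first "
            f"event at t={first}"
        )
    # clamp the pre-contraction sample/anchor to after genetics activation,
    # and the ancestry times inside the run (matters only for short profiles)
    pre_t = max(first - 50, inject + 1)
    end = final + params.post_run
    snapshots = {PRE_LABEL: (pre_t, 100)}
    for k, (et, _) in enumerate(schedule.events, start=1):
        snapshots[f"post_event_{k}"] = (et + 50, 100)
    snapshots[FINAL_LABEL] = (end, 100)
    return SamplingPlan(
        inject_time=inject,
        snapshots=snapshots,
        region_time=end,
        region_groups=region_groups_for(schedule.pattern, schedule.nx, schedule.ny),
        region_n=50,
        anchor_times=(pre_t, min(final + 50, end)),
        descendant_time=min(final + 100, end),
        n_descendants=4,
        relatedness_start=max(first - 100, inject),
    )


def run_replicate(
    scenario: str,
    params: SimParams,
    seed: int,
    nx: int = 20,
    ny: int = 20,
    n_events: int = 4,
    frac_per_event: float = 0.22,
    interval: int = 100,
    schedule: ContractionSchedule | None = None,
) -> SimResult:
    """Run one replicate of one scenario with the default sampling plan."""
    if schedule is None:
        schedule = make_schedule(
            scenario, nx, ny, n_events=n_events, frac_per_event=frac_per_event,
            interval=interval, start=params.burn_in, seed=seed,
        )
    grid = build_grid(schedule.nx, schedule.ny)
    plan = build_sampling_plan(params, schedule)
    return simcore.run(params, schedule, grid, seed, plan)


# ---------------------------------------------------------------------------
# per-replicate analysis


def _snapshot_diversity(result: SimResult) -> pd.DataFrame:
    """Heterozygosity / diversity table for the timed random snapshots."""
    G = float(result.params.genome_length)
    rows = []
    hets = {}
    for label, grp in sorted(result.samples.items(), key=lambda kv: kv[1].timestep):
        h = pg.group_heterozygosities(grp.haplotypes, G)
        hets[label] = h
        rows.append(
            {
                "label": label,
                "t": grp.timestep,
                "n": grp.n,
                "mean_het": float(h.mean()) if grp.n else np.nan,
                "group_pi": pg.nucleotide_diversity(grp.haplotypes, G) if grp.n >= 2 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if PRE_LABEL in hets and len(df):
        pre = float(np.mean(hets[PRE_LABEL]))
        df["rel_het"] = df["mean_het"] / pre
        pmat = pg.pairwise_wilcoxon({k: v for k, v in hets.items() if len(v) >= 2})
        df["p_vs_pre"] = [
            pmat.loc[lab, PRE_LABEL] if lab != PRE_LABEL and lab in pmat.index else np.nan
            for lab in df["label"]
        ]
    return df


def _region_fst(result: SimResult) -> pd.DataFrame:
    """Pairwise pi12 / F_ST among region groups plus the ancient baseline."""
    G = float(result.params.genome_length)
    groups: dict = {}
    for name, grp in result.region_samples.items():
        if grp.n >= 2:
            groups[name] = grp
        else:
            log.warning("region %s has %d individuals; skipped", name, grp.n)
    pre = result.samples.get(PRE_LABEL)
    if pre is not None and pre.n >= 2:
        k = min(50, pre.n)
        groups["ancient"] = SampleGroup(
            "ancient", pre.timestep, pre.ids[:k], pre.x[:k], pre.y[:k],
            pre.haplotypes[:k], requested_n=50,
        )
    names = list(groups)
    pis = {nm: pg.nucleotide_diversity(groups[nm].haplotypes, G) for nm in names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ga, gb = groups[a], groups[b]
            pi12 = pg.pairwise_divergence(ga.haplotypes, gb.haplotypes, G)
            dist = np.nan
            if "ancient" not in (a, b):
                dist = float(
                    np.hypot(ga.x.mean() - gb.x.mean(), ga.y.mean() - gb.y.mean())
                )
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "n1": ga.n,
                    "n2": gb.n,
                    "pi1": pis[a],
                    "pi2": pis[b],
                    "pi12": pi12,
                    "fst": pg.fst(pis[a], pis[b], pi12),
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows)


def _decline(result: SimResult) -> dict:
    """Population decline from the pre-contraction mean to the final window."""
    ts = result.timeseries
    first = result.schedule.first_event_time
    if first is None:
        first = result.params.burn_in
    pre = ts.loc[(ts.t >= first - 100) & (ts.t < first), "n"].mean()
    post = ts.loc[ts.t > ts.t.max() - 50, "n"].mean()
    return {"pre_n": float(pre), "post_n": float(post), "decline": float(1.0 - post / pre)}


def _relatedness_trend(result: SimResult) -> dict:
    """OLS of F_r on timestep over the contraction-and-after window."""
    ts = result.timeseries
    first = result.schedule.first_event_time
    if first is None:
        first = result.params.burn_in
    sub = ts.loc[(ts.t >= first) & ts.fr.notna()]
    if len(sub) < 3:
        return {"fr_slope": np.nan, "fr_r2": np.nan, "fr_p": np.nan}
    fit = pg.trend_fit(sub.t, sub.fr)
    return {"fr_slope": fit.slope, "fr_r2": fit.r_squared, "fr_p": fit.pvalue}


def ancestry_cloud(result: SimResult) -> pd.DataFrame:
    """Ancestor locations weighted by genomic contribution, per slice.

    One row per (descendant, slice, ancestor): the ancestor's position at
    the slice time and the fraction of the descendant's genome it carried
    then.  Fractions sum to 1 per descendant per slice.
    """
    G = float(result.params.genome_length)
    rows = []
    for slice_t, snap in result.anchors.items():
        pos = {int(i): (float(x), float(y)) for i, x, y in zip(snap["ids"], snap["x"], snap["y"])}
        for did, dx, dy, haps in result.descendants:
            contribs = ancestry_contributions(haps, slice_t, G)
            for anc, frac in sorted(contribs.items()):
                ax, ay = pos[anc]
                rows.append(
                    {
                        "descendant_id": did,
                        "descendant_x": dx,
                        "descendant_y": dy,
                        "slice_time": slice_t,
                        "ancestor_id": anc,
                        "ancestor_x": ax,
                        "ancestor_y": ay,
                        "fraction": frac,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the experiment


@dataclass
class ExperimentResult:
    """Aggregated products of a scenario x replicate grid."""

    scenarios: list
    n_replicates: int
    master_seed: int
    params: SimParams
    seeds: pd.DataFrame
    timeseries: pd.DataFrame
    diversity: pd.DataFrame
    fst: pd.DataFrame
    declines: pd.DataFrame
    relatedness: pd.DataFrame
    ancestry: pd.DataFrame
    extinctions: list = field(default_factory=list)
    results: dict = field(default_factory=dict)  # (scenario, rep) -> SimResult if kept


def replicate_seed(master_seed: int, scenario: str, rep: int) -> int:
    """Deterministic per-run seed derived from the master seed (< 2^31)."""
    scen_key = zlib.crc32(scenario.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([master_seed, scen_key, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_experiment(
    scenarios,
    n_replicates: int,
    params: SimParams,
    master_seed: int,
    nx: int = 20,
    ny: int = 20,
    keep_results: bool = False,
    **schedule_kwargs,
) -> ExperimentResult:
    """Run the full scenario x replicate grid and aggregate the analyses.

    Replicates that go extinct are recorded in ``extinctions`` and excluded
    from aggregate tables (with a warning).  All outputs are deterministic
    given ``master_seed``.
    """
    scenarios = list(scenarios)
    seed_rows, ts_rows, div_rows, fst_rows, dec_rows, rel_rows, anc_rows = (
        [], [], [], [], [], [], []
    )
    extinctions = []
    kept = {}
    for scen in scenarios:
        for rep in range(n_replicates):
            seed = replicate_seed(master_seed, scen, rep)
            seed_rows.append({"scenario": scen, "replicate": rep, "seed": seed})
            log.info("running %s replicate %d (seed %d)", scen, rep, seed)
            res = run_replicate(scen, params, seed, nx=nx, ny=ny, **schedule_kwargs)
            if keep_results:
                kept[(scen, rep)] = res
            ts = res.timeseries.copy()
            ts.insert(0, "scenario", scen)
            ts.insert(1, "replicate", rep)
            ts_rows.append(ts)
            if res.extinct:
                log.warning(
                    "%s replicate %d went extinct at t=%s; excluded from aggregates",
                    scen, rep, res.extinct_at,
                )
                extinctions.append({"scenario": scen, "replicate": rep, "t": res.extinct_at})
                continue
            for df, sink in ((_snapshot_diversity(res), div_rows), (_region_fst(res), fst_rows)):
                df.insert(0, "scenario", scen)
                df.insert(1, "replicate", rep)
                sink.append(df)
            dec_rows.append({"scenario": scen, "replicate": rep, **_decline(res)})
            rel_rows.append({"scenario": scen, "replicate": rep, **_relatedness_trend(res)})
            anc = ancestry_cloud(res)
            if len(anc):
                anc.insert(0, "scenario", scen)
                anc.insert(1, "replicate", rep)
                anc_rows.append(anc)
    cat = lambda rows: pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return ExperimentResult(
        scenarios=scenarios,
        n_replicates=n_replicates,
        master_seed=master_seed,
        params=params,
        seeds=pd.DataFrame(seed_rows),
        timeseries=cat(ts_rows),
        diversity=cat(div_rows),
        fst=cat(fst_rows),
        declines=pd.DataFrame(dec_rows),
        relatedness=pd.DataFrame(rel_rows),
        ancestry=cat(anc_rows),
        extinctions=extinctions,
        results=kept,
    )


# ---------------------------------------------------------------------------
# figure/table-equivalent summaries


def diversity_timecourse(experiment: ExperimentResult) -> pd.DataFrame:
    """Relative diversity per scenario and sampling point, across replicates.

    Mean individual heterozygosity relative to the replicate's own
    pre-contraction mean, averaged over replicates, with the fraction of
    replicates in which the point is significantly below the baseline
    (Holm-adjusted rank-sum p < 0.05).
    """
    d = experiment.diversity
    if not len(d):
        return pd.DataFrame()
    d = d[d.label != PRE_LABEL]
    agg = (
        d.groupby(["scenario", "label"], as_index=False)
        .agg(
            t=("t", "first"),
            rel_het=("rel_het", "mean"),
            rel_het_sd=("rel_het", "std"),
            signif_frac=("p_vs_pre", lambda p: float(np.mean(np.asarray(p) < 0.05))),
            n_replicates=("replicate", "count"),
        )
        .sort_values(["scenario", "t"])
        .reset_index(drop=True)
    )
    return agg


def decline_summary(experiment: ExperimentResult) -> pd.DataFrame:
    """Mean population decline per scenario."""
    return (
        experiment.declines.groupby("scenario", as_index=False)
        .agg(decline=("decline", "mean"), decline_sd=("decline", "std"),
             pre_n=("pre_n", "mean"), post_n=("post_n", "mean"))
    )


def percent_diversity_decrease(experiment: ExperimentResult, scenario: str,
                               label: str = FINAL_LABEL) -> float:
    """Mean percent decrease of diversity vs the pre-contraction baseline."""
    d = experiment.diversity
    sel = d[(d.scenario == scenario) & (d.label == label)]
    if not len(sel):
        raise ValueError(f"no diversity rows for {scenario}/{label}")
    return float(100.0 * (1.0 - sel.rel_het.mean()))


def fragmentation_min_fst(experiment: ExperimentResult,
                          scenario: str = "fragmentation") -> float:
    """Mean over replicates of the minimum pairwise F_ST among remnant patches."""
    f = experiment.fst
    sel = f[(f.scenario == scenario) & (f.group1 != "ancient") & (f.group2 != "ancient")]
    if not len(sel):
        raise ValueError(f"no patch F_ST rows for {scenario}")
    return float(sel.groupby("replicate").fst.min().mean())


def ibd_correlation(experiment: ExperimentResult, scenario: str) -> pd.DataFrame:
    """Isolation by distance: Spearman correlation of F_ST with distance.

    One row per replicate, plus whether the largest F_ST falls on the most
    distant group pair.
    """
    f = experiment.fst
    sel = f[(f.scenario == scenario) & f.distance.notna()]
    rows = []
    for rep, sub in sel.groupby("replicate"):
        rho, p = sps.spearmanr(sub.distance, sub.fst)
        imax = sub.fst.idxmax()
        rows.append(
            {
                "scenario": scenario,
                "replicate": rep,
                "spearman_rho": float(rho),
                "spearman_p": float(p),
                "max_fst_is_most_distant": bool(
                    sub.loc[imax, "distance"] == sub.distance.max()
                ),
            }
        )
    return pd.DataFrame(rows)


def aggregate_timeseries(experiment: ExperimentResult) -> pd.DataFrame:
    """Per-timestep mean and s.d. across replicates, per scenario."""
    ts = experiment.timeseries
    return (
        ts.groupby(["scenario", "t"], as_index=False)
        .agg(
            n_mean=("n", "mean"), n_sd=("n", "std"),
            mean_age=("mean_age", "mean"), mean_age_sd=("mean_age", "std"),
            max_age=("max_age", "mean"),
            mean_offspring=("mean_offspring", "mean"),
            fr=("fr", "mean"),
        )
    )
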