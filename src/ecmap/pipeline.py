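"""End-to-end cohort analysis: prewhiten -> FC -> ECM -> hubs -> nulls -> scores.

The driver is a pure function of (inputs, configuration): every stochastic
step draws its seed from one root seed in a fixed order, so identical
configurations produce byte-identical result JSON. Hubs enter the behavioral
correlation stage when they satisfy the hub criterion in *either* group in
*either* scan — membership never depends on a group difference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ROITimeSeries, read_roi_timeseries
from .behavioral import behavioral_scores, correlate_scores_with_ec, read_vf_csv
from .centrality import HubSet, compare_hub_ec, ec_from_ts, identify_hubs
from .connectivity import fc_matrix, participant_fc_summary, whole_brain_fc_test
from .nulls import SurrogateConfig, bootstrap_ec_distribution, surrogate_ec_distribution
from .prewhiten import ConfoundSet, prewhiten_pipeline
from .synthetic import SimConfig, simulate_cohort

SCANS = ("RS1", "RS2")


@dataclass
class AnalysisParams:
    """All analysis knobs; defaults are the package's standard settings."""

    percentile: float = 95.0
    n_perm: int = 10_000
    whole_brain_statistic: str = "diff_of_medians"
    hub_statistic: str = "diff_of_means"
    fwe: str = "max_stat"
    n_surrogates: int = 15
    surrogate_max_iter: int = 15
    n_boot: int = 50
    nulls_scans: tuple[str, ...] = ("RS1", "RS2")
    pooled_phi: bool = False
    scaled_first_row: bool = False
    bootstrap_block: bool = False
    group_ec_of_mean_matrix: bool = False
    seed: int = 0


@dataclass
class RunConfig:
    """Run configuration: either a simulation block or input paths."""

    simulate: dict | None = None
    inputs: dict | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"simulate", "inputs", "analysis"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        analysis_raw = dict(raw.get("analysis") or {})
        valid = {f.name for f in fields(AnalysisParams)}
        bad = set(analysis_raw) - valid
        if bad:
            raise ValueError(f"unknown analysis key(s): {sorted(bad)}")
        if "nulls_scans" in analysis_raw:
            analysis_raw["nulls_scans"] = tuple(analysis_raw["nulls_scans"])
        sim = raw.get("simulate")
        if sim is not None:
            valid_sim = {f.name for f in fields(SimConfig)}
            bad = set(sim) - valid_sim
            if bad:
                raise ValueError(f"unknown simulate key(s): {sorted(bad)}")
        return cls(simulate=sim, inputs=raw.get("inputs"),
                   analysis=AnalysisParams(**analysis_raw))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        d = {"simulate": self.simulate, "inputs": self.inputs,
             "analysis": asdict(self.analysis)}
        d["analysis"]["nulls_scans"] = list(self.analysis.nulls_scans)
        return d


def _load_input_cohort(inputs: dict):
    """Load participant bundles from on-disk TSV/CSV per the I/O conventions."""
    from .synthetic import ParticipantBundle

    root = Path(inputs["dir"])
    groups = pd.read_csv(root / "groups.tsv", sep="\t")
    bundles = []
    for row in groups.itertuples(index=False):
        pid = str(row.participant_id)
        scans = {}
        for scan in SCANS:
            ts_path = root / f"{pid}_{scan}.tsv"
            if not ts_path.exists():
                continue
            ts = read_roi_timeseries(ts_path)
            conf_df = pd.read_csv(root / f"{pid}_{scan}_confounds.tsv", sep="\t")
            conf = ConfoundSet(
                motion=conf_df[["trans_x", "trans_y", "trans_z",
                                "rot_x", "rot_y", "rot_z"]].to_numpy(float),
                wm=conf_df["wm"].to_numpy(float),
                csf=conf_df["csf"].to_numpy(float),
                participant_id=pid,
            )
            scans[scan] = (ts, conf)
        vf_l = vf_r = None
        if (root / f"{pid}_left.csv").exists() and (root / f"{pid}_right.csv").exists():
            vf_l = read_vf_csv(root / f"{pid}_left.csv")
            vf_r = read_vf_csv(root / f"{pid}_right.csv")
        bundles.append(ParticipantBundle(
            participant_id=pid, group=str(row.group), severity=float("nan"),
            asymmetry=float("nan"), scans=scans, vf_left=vf_l, vf_right=vf_r,
        ))
    return bundles, None


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the result.

    Stage order: prewhitening, functional connectivity, whole-brain group
    test, eigenvector centrality, hub identification per group and scan, hub
    union, hub group comparison, surrogate/bootstrap null distributions,
    behavioral scores and hub-score Spearman correlations.
    """
    p = cfg.analysis
    ss = np.random.SeedSequence(p.seed)
    # fixed spawn order: [whole-brain RS1, RS2, hub-compare RS1, RS2,
    #                     surrogate RS1, RS2, bootstrap RS1, RS2]
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    seed_map = dict(zip(
        ["whole_brain_RS1", "whole_brain_RS2", "hub_compare_RS1",
         "hub_compare_RS2", "surrogate_RS1", "surrogate_RS2",
         "bootstrap_RS1", "bootstrap_RS2"], seeds))

    if cfg.simulate is not None:
        bundles, truth = simulate_cohort(SimConfig(**cfg.simulate))
    elif cfg.inputs is not None:
        bundles, truth = _load_input_cohort(cfg.inputs)
    else:
        raise ValueError("config must provide either 'simulate' or 'inputs'")

    scan_names = [s for s in SCANS if all(s in b.scans for b in bundles)]
    if not scan_names:
        raise ValueError("no scan present for every participant")
    group_names = sorted({b.group for b in bundles})

    # --- per-participant prewhitening, FC and EC --------------------------
    clean: dict[str, dict[str, ROITimeSeries]] = {s: {} for s in scan_names}
    fc_sum: dict[str, dict[str, float]] = {s: {} for s in scan_names}
    roi_mean_fc: dict[str, dict[str, np.ndarray]] = {s: {} for s in scan_names}
    ec_rows: dict[str, dict[str, np.ndarray]] = {s: {} for s in scan_names}
    roi_ids = None
    for b in bundles:
        for scan in scan_names:
            ts, conf = b.scans[scan]
            try:
                cts = prewhiten_pipeline(ts, conf, pooled_phi=p.pooled_phi,
                                         scaled_first_row=p.scaled_first_row)
                fc = fc_matrix(cts)
                ec = ec_from_ts(cts)
            except Exception as exc:  # contract: name stage and participant
                raise RuntimeError(
                    f"stage failure for participant {b.participant_id!r}, "
                    f"scan {scan}: {exc}"
                ) from exc
            clean[scan][b.participant_id] = cts
            fc_sum[scan][b.participant_id] = participant_fc_summary(fc)
            z = fc.z.copy()
            np.fill_diagonal(z, np.nan)
            roi_mean_fc[scan][b.participant_id] = np.nanmean(z, axis=0)
            ec_rows[scan][b.participant_id] = ec.ec
            roi_ids = cts.roi_ids
    ec_tables = {
        scan: pd.DataFrame.from_dict(ec_rows[scan], orient="index",
                                     columns=roi_ids)
        for scan in scan_names
    }
    group_of = {b.participant_id: b.group for b in bundles}

    result: dict = {
        "manifest": {
            "version": __version__,
            "config": cfg.to_dict(),
            "seeds": seed_map,
            "n_participants": len(bundles),
            "groups": {g: sum(1 for b in bundles if b.group == g)
                       for g in group_names},
            "scans": scan_names,
        },
        "scans": {},
    }

    all_hubs: list[int] = []
    for scan in scan_names:
        pids_by_group = {g: [b.participant_id for b in bundles if b.group == g]
                         for g in group_names}
        scan_res: dict = {"fc_summary": {pid: fc_sum[scan][pid]
                                         for pid in sorted(fc_sum[scan])}}
        # whole-brain FC comparison (two groups only)
        if len(group_names) == 2 and all(len(v) >= 2 for v in pids_by_group.values()):
            g0, g1 = group_names
            wb = whole_brain_fc_test(
                [fc_sum[scan][pid] for pid in pids_by_group[g0]],
                [fc_sum[scan][pid] for pid in pids_by_group[g1]],
                n_perm=p.n_perm, seed=seed_map[f"whole_brain_{scan}"],
                statistic=p.whole_brain_statistic,
            )
            scan_res["whole_brain"] = {
                "groups": [g0, g1], "observed": float(wb.observed[0]),
                "p": float(wb.p_raw[0]), "statistic": p.whole_brain_statistic,
                "n_perm": wb.n_perm,
            }
        # per-group mean FC per ROI (for reporting) and hubs
        scan_res["group_roi_fc"] = {}
        scan_res["group_ec"] = {}
        scan_res["hubs"] = {}
        for g in group_names:
            pids = pids_by_group[g]
            scan_res["group_roi_fc"][g] = np.mean(
                [roi_mean_fc[scan][pid] for pid in pids], axis=0).tolist()
            if p.group_ec_of_mean_matrix:
                # centrality of the group-mean adjacency (alternative rule)
                from .centrality import adjacency_from_ts, eigenvector_centrality
                adjs = [adjacency_from_ts(clean[scan][pid]).a for pid in pids]
                gec = eigenvector_centrality(np.mean(adjs, axis=0)).ec
            else:
                gec = ec_tables[scan].loc[pids].mean(axis=0).to_numpy()
            hubs = identify_hubs(gec, roi_ids=roi_ids, percentile=p.percentile)
            scan_res["group_ec"][g] = gec.tolist()
            scan_res["hubs"][g] = {
                "roi_ids": hubs.roi_ids, "threshold": hubs.threshold,
                "percentile": hubs.percentile,
            }
            all_hubs.extend(hubs.roi_ids)
        result["scans"][scan] = scan_res

    # hub union across groups and scans: membership depends only on the hub
    # criterion per scan, never on a group difference
    hub_union = sorted(set(all_hubs))
    result["hub_union"] = hub_union
    union_set = HubSet(roi_ids=hub_union, threshold=float("nan"),
                       percentile=cfg.analysis.percentile)

    for scan in scan_names:
        if len(group_names) != 2:
            break
        g0, g1 = group_names
        pids0 = [b.participant_id for b in bundles if b.group == g0]
        pids1 = [b.participant_id for b in bundles if b.group == g1]
        if min(len(pids0), len(pids1)) < 2:
            break
        comp = compare_hub_ec(
            ec_tables[scan].loc[pids0], ec_tables[scan].loc[pids1],
            union_set, n_perm=p.n_perm, seed=seed_map[f"hub_compare_{scan}"],
        )
        result["scans"][scan]["hub_comparison"] = {
            "groups": [g0, g1], "hubs": hub_union,
            "observed": comp.observed.tolist(),
            "p_raw": comp.p_raw.tolist(), "p_fwe": comp.p_fwe.tolist(),
            "n_perm": comp.n_perm,
        }

    # --- surrogate and bootstrap distributions per group ------------------
    result["nulls"] = {}
    for scan in [s for s in p.nulls_scans if s in scan_names]:
        result["nulls"][scan] = {}
        for g in group_names:
            cohort = [clean[scan][b.participant_id] for b in bundles
                      if b.group == g]
            sur = surrogate_ec_distribution(
                cohort, SurrogateConfig(n_surrogates=p.n_surrogates,
                                        max_iter=p.surrogate_max_iter,
                                        seed=seed_map[f"surrogate_{scan}"]))
            boot = bootstrap_ec_distribution(
                cohort, n_boot=p.n_boot, seed=seed_map[f"bootstrap_{scan}"],
                block=p.bootstrap_block)
            result["nulls"][scan][g] = {
                "hubs": hub_union,
                "surrogate_mu": [float(sur.gauss_mu[roi_ids.index(h)])
                                 for h in hub_union],
                "surrogate_sigma": [float(sur.gauss_sigma[roi_ids.index(h)])
                                    for h in hub_union],
                "bootstrap_mu": [float(boot.gauss_mu[roi_ids.index(h)])
                                 for h in hub_union],
                "bootstrap_sigma": [float(boot.gauss_sigma[roi_ids.index(h)])
                                    for h in hub_union],
                "n_surrogates": p.n_surrogates, "n_boot": p.n_boot,
            }

    # --- behavioral scores and correlations -------------------------------
    scores = pd.DataFrame(
        {b.participant_id: behavioral_scores(b.vf_left, b.vf_right,
                                             b.participant_id).as_dict()
         for b in bundles}
    ).T
    result["behavioral"] = {
        "scores": {pid: {k: (None if pd.isna(v) else float(v))
                         for k, v in row.items()}
                   for pid, row in scores.iterrows()},
        "group_medians": {
            g: {c: (None if pd.isna(m) else float(m))
                for c, m in scores.loc[[pid for pid, gg in group_of.items()
                                        if gg == g]].median().items()}
            for g in group_names
        },
    }
    result["correlations"] = {}
    for scan in scan_names:
        corr = correlate_scores_with_ec(scores, ec_tables[scan], union_set)
        result["correlations"][scan] = corr.to_dict(orient="records")

    result = _round_floats(result)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "result.json").write_text(
            json.dumps(result, sort_keys=True, indent=2) + "\n")
        for scan in scan_names:
            ec_tables[scan].to_csv(out_dir / f"ec_{scan}.tsv", sep="\t")
    return result


def report(result: dict, out_dir: str | Path) -> list[Path]:
    """Write summary figures and a text digest; purely presentational."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scans = list(result.get("scans", {}))

    # FC distribution across ROIs per group and scan
    fig, ax = plt.subplots(figsize=(6, 4))
    for scan in scans:
        for g, vals in result["scans"][scan].get("group_roi_fc", {}).items():
            ax.hist(vals, bins=30, histtype="step", label=f"{g} {scan}")
    ax.set_xlabel("mean Fisher-z FC per ROI")
    ax.set_ylabel("count")
    if ax.get_legend_handles_labels()[1]:
        ax.legend(fontsize=7)
    p = out_dir / "fc_distributions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # test-retest EC scatter with linear fit
    if len(scans) >= 2:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        groups = list(result["scans"][scans[0]].get("group_ec", {}))
        for ax, g in zip(axes, groups):
            x = np.asarray(result["scans"][scans[0]]["group_ec"][g])
            y = np.asarray(result["scans"][scans[1]]["group_ec"][g])
            slope, intercept = np.polyfit(x, y, 1)
            ax.plot(x, y, ".", ms=4)
            xs = np.linspace(x.min(), x.max(), 10)
            ax.plot(xs, slope * xs + intercept, "k-", lw=1)
            ax.set_title(f"{g}: slope {slope:.2f}")
            ax.set_xlabel(f"EC {scans[0]}")
            ax.set_ylabel(f"EC {scans[1]}")
        fig.tight_layout()
        p = out_dir / "ec_test_retest.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    # null/bootstrap Gaussian overlays per hub
    for scan, per_group in result.get("nulls", {}).items():
        hubs = result.get("hub_union", [])
        if not hubs or not per_group:
            continue
        n = len(hubs)
        fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
        for i, h in enumerate(hubs):
            ax = axes[0][i]
            for g, d in per_group.items():
                for kind, style in (("surrogate", "--"), ("bootstrap", "-")):
                    mu = d[f"{kind}_mu"][i]
                    sd = max(d[f"{kind}_sigma"][i], 1e-12)
                    xs = np.linspace(mu - 4 * sd, mu + 4 * sd, 100)
                    ax.plot(xs, np.exp(-((xs - mu) ** 2) / (2 * sd**2))
                            / (sd * np.sqrt(2 * np.pi)), style,
                            label=f"{g} {kind}", lw=1)
            ax.set_title(f"hub {h}", fontsize=8)
        axes[0][0].legend(fontsize=6)
        fig.tight_layout()
        p = out_dir / f"null_distributions_{scan}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    # score vs EC scatters are derived from the correlations table
    lines = ["ecmap run summary", "=================", ""]
    for scan in scans:
        wb = result["scans"][scan].get("whole_brain")
        if wb:
            lines.append(f"{scan} whole-brain FC ({wb['statistic']}): "
                         f"diff {wb['observed']:+.4f}, p = {wb['p']:.4f}")
        for g, h in result["scans"][scan].get("hubs", {}).items():
            lines.append(f"{scan} {g} hubs: {h['roi_ids']} "
                         f"(threshold {h['threshold']:.5f})")
    lines.append(f"hub union: {result.get('hub_union', [])}")
    for scan, recs in result.get("correlations", {}).items():
        sig = [r for r in recs if r["p"] is not None and not pd.isna(r["p"])
               and r["p"] <= 0.05]
        lines.append(f"{scan}: {len(sig)} significant hub-score correlations")
        for r in sig:
            lines.append(f"  hub {r['hub']} ~ {r['score']}: rho {r['rho']:+.3f}, "
                         f"p {r['p']:.4f} (n={r['n']})")
    p = out_dir / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
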