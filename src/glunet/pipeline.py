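"""Full-pipeline orchestration from a single YAML config.

Stages: simulate (or load) -> metabolism -> networks -> metrics -> hubs ->
permutation -> rich club -> PLSR.  Every stochastic stage draws its seed
deterministically from the config's master seed, all artifacts are CSV/JSON
under the output directory, and a rerun with an identical config is
bit-identical (timings are confined to the run log).
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, metrics, networks, nulls, plsr, stats, synthetic
from .io import ValidationError


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    seed: int
    synthetic_spec: dict = dataclasses.field(default_factory=dict)
    cohort_paths: dict | None = None  # {'uptake':..., 'metadata':..., 'regions':...}
    t_min: float = 0.49
    t_step: float = 0.01
    hard_max: float = 0.95
    n_null: int = 1000
    n_perm: int = 5000
    er_null_size: int = 200
    n_rewire_null: int = 1000
    n_components: int = 2
    alpha: float = 0.05
    network_groups: tuple = (("WT", "SAL"), ("HET", "SAL"))
    drug_group: tuple = ("HET", "KET")
    plsr_seed_regions: tuple | None = None  # defaults to seeds of planted lost edges
    designs: tuple = (("SAL", "KET"), ("SAL", "AMPH"))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seed" not in d or d["seed"] is None:
            raise ValidationError("pipeline config must set an explicit seed")
        if "out_dir" not in d:
            raise ValidationError("pipeline config must set out_dir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("network_groups", "designs"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        if "drug_group" in d:
            d["drug_group"] = tuple(d["drug_group"])
        if d.get("plsr_seed_regions") is not None:
            d["plsr_seed_regions"] = tuple(int(r) for r in d["plsr_seed_regions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _child_seeds(master: int, n: int):
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t0 = time.time()

    def log(stage, seed=None, **info):
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), "seed": seed}
        entry.update(info)
        log_lines.append(json.dumps(entry))

    seeds = _child_seeds(config.seed, 6)
    summary = {"seed": config.seed, "stage_seeds": seeds}

    # --- stage: cohort -----------------------------------------------------
    stage = "cohort"
    try:
        if config.cohort_paths:
            cohort = io.read_cohort(
                config.cohort_paths["uptake"],
                config.cohort_paths["metadata"],
                config.cohort_paths["regions"],
            )
            spec = None
        else:
            spec_kwargs = dict(config.synthetic_spec)
            spec_kwargs.setdefault("seed", seeds[0])
            spec = synthetic.SyntheticSpec.from_dict(spec_kwargs)
            cohort = synthetic.generate_cohort(spec)
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        io.write_cohort(
            cohort, cdir / "uptake.csv", cdir / "metadata.csv", cdir / "regions.csv"
        )
        if spec is not None:
            with open(cdir / "ground_truth.yaml", "w") as fh:
                yaml.safe_dump(synthetic.ground_truth(spec), fh)
        log(stage, seed=seeds[0], n_animals=cohort.n_animals, n_regions=cohort.n_regions)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: metabolism -------------------------------------------------
    stage = "metabolism"
    try:
        rows = []
        for treatments in config.designs:
            for region in range(cohort.n_regions):
                res = stats.factorial_anova(
                    cohort, region, factors=("sex", "genotype", "treatment"),
                    treatments=treatments,
                )
                for effect, er in res.effects.items():
                    rows.append(
                        {
                            "design": "-".join(treatments),
                            "region": cohort.regions.abbreviation[region],
                            "effect": effect,
                            "F": er.F,
                            "df_num": er.df_num,
                            "df_den": er.df_den,
                            "p": er.p,
                        }
                    )
        anova_df = pd.DataFrame(rows)
        (out / "metabolism").mkdir(exist_ok=True)
        anova_df.to_csv(out / "metabolism" / "anova.csv", index=False)
        log(stage, n_rows=len(anova_df))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: networks ---------------------------------------------------
    stage = "networks"
    try:
        nets = {
            g: networks.correlation_matrix(cohort, g) for g in config.network_groups
        }
        grid = networks.select_threshold_grid(
            list(nets.values()), config.t_min, config.t_step, config.hard_max
        )
        nets = {g: networks.threshold_adjacency(net, grid) for g, net in nets.items()}
        ndir = out / "networks"
        ndir.mkdir(exist_ok=True)
        for g, net in nets.items():
            tag = "_".join(g)
            abbr = list(cohort.regions.abbreviation)
            pd.DataFrame(net.R, index=abbr, columns=abbr).to_csv(
                ndir / f"R_{tag}.csv", float_format="%.17g"
            )
            io.write_edge_list(net, 0, ndir / f"edges_{tag}_t0.csv")
        np.savetxt(ndir / "thresholds.csv", grid, fmt="%.10g")
        summary["threshold_grid"] = [float(t) for t in grid]
        log(stage, grid=[float(t) for t in grid])
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: metrics ----------------------------------------------------
    stage = "metrics"
    try:
        mdir = out / "metrics"
        mdir.mkdir(exist_ok=True)
        profiles = {}
        grows = []
        crows = []
        for g, net in nets.items():
            profile = metrics.centrality_profile(net.A, grid)
            profiles[g] = profile
            for ti, t in enumerate(grid):
                gm = metrics.global_metrics(net.A[ti])
                grows.append(
                    {
                        "group": "/".join(g),
                        "threshold": float(t),
                        "mean_degree": gm.mean_degree,
                        "path_length": gm.path_length,
                        "clustering": gm.clustering,
                    }
                )
                for r in range(cohort.n_regions):
                    crows.append(
                        {
                            "group": "/".join(g),
                            "threshold": float(t),
                            "region": cohort.regions.abbreviation[r],
                            "degree": float(profile.degree[ti, r]),
                            "betweenness": float(profile.betweenness[ti, r]),
                            "eigenvector": float(profile.eigenvector[ti, r]),
                        }
                    )
        gdf = pd.DataFrame(grows)
        gdf.to_csv(mdir / "global.csv", index=False)
        pd.DataFrame(crows).to_csv(mdir / "centrality.csv", index=False)
        summary["global_metrics"] = {
            "/".join(g): {
                m: float(gdf[gdf["group"] == "/".join(g)][m].mean())
                for m in ("mean_degree", "path_length", "clustering")
            }
            for g in nets
        }
        log(stage)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: hubs -------------------------------------------------------
    stage = "hubs"
    try:
        hdir = out / "hubs"
        hdir.mkdir(exist_ok=True)
        hub_summary = {}
        for gi, (g, net) in enumerate(nets.items()):
            table = nulls.er_null_z(
                profiles[g], net.A, n_null=config.n_null, seed=seeds[1] + gi
            )
            rows = []
            for r in range(cohort.n_regions):
                rows.append(
                    {
                        "region": cohort.regions.abbreviation[r],
                        **{
                            f"mean_z_{m}": float(table.mean_z[m][r])
                            for m in nulls.CENTRALITY_METRICS
                        },
                        **{
                            f"hub_{m}": bool(table.hub[m][r])
                            for m in nulls.CENTRALITY_METRICS
                        },
                    }
                )
            pd.DataFrame(rows).to_csv(hdir / ("hubs_" + "_".join(g) + ".csv"), index=False)
            hub_summary["/".join(g)] = {
                m: [
                    cohort.regions.abbreviation[r]
                    for r in np.flatnonzero(table.hub[m])
                ]
                for m in nulls.CENTRALITY_METRICS
            }
        summary["hubs"] = hub_summary
        log(stage, seed=seeds[1], n_null_graphs=config.n_null * len(grid))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: permutation ------------------------------------------------
    stage = "permutation"
    try:
        pdir = out / "permutation"
        pdir.mkdir(exist_ok=True)
        ga, gb = config.network_groups[:2]
        perm_rows = []
        dropped = {}
        for si, statistic in enumerate(nulls.GLOBAL_STATISTICS):
            outcome = nulls.permute_groups(
                cohort, ga, gb, statistic, grid,
                n_perm_per_threshold=config.n_perm,
                seed=seeds[2] + si,
                er_null_size=config.er_null_size,
            )
            perm_rows.append(
                {
                    "statistic": statistic,
                    "real_difference": outcome.real,
                    "p": outcome.p,
                    "n_perm_per_threshold": outcome.n_perm_per_threshold,
                    "n_evaluated": outcome.n_evaluated,
                    "n_dropped": outcome.n_dropped,
                }
            )
            dropped[statistic] = outcome.n_dropped
        pdf = pd.DataFrame(perm_rows)
        pdf.to_csv(pdir / "global_permutation.csv", index=False)
        summary["permutation"] = {
            row["statistic"]: {"difference": row["real_difference"], "p": row["p"]}
            for row in perm_rows
        }
        log(stage, seed=seeds[2], dropped=dropped)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: richclub ---------------------------------------------------
    stage = "richclub"
    try:
        rdir = out / "richclub"
        rdir.mkdir(exist_ok=True)
        rc_summary = {}
        for gi, (g, net) in enumerate(nets.items()):
            res = nulls.rich_club_core(
                net.A, grid, n_rewire_null=config.n_rewire_null, seed=seeds[3] + gi
            )
            rows = []
            for ti, levels in enumerate(res.per_threshold):
                for lv in levels:
                    rows.append(
                        {
                            "threshold": float(grid[ti]),
                            "k": lv.k,
                            "n_nodes": lv.n_nodes,
                            "phi": lv.phi,
                            "phi_rand_mean": lv.phi_rand_mean,
                            "phi_norm": lv.phi_norm,
                            "p": lv.p,
                            "approximate_algorithm": True,
                        }
                    )
            pd.DataFrame(rows).to_csv(
                rdir / ("richclub_" + "_".join(g) + ".csv"), index=False
            )
            rc_summary["/".join(g)] = sorted(
                cohort.regions.abbreviation[r] for r in res.rcc
            )
        summary["rich_club_core"] = rc_summary
        log(stage, seed=seeds[3])
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: plsr -------------------------------------------------------
    stage = "plsr"
    try:
        sdir = out / "plsr"
        sdir.mkdir(exist_ok=True)
        if config.plsr_seed_regions is not None:
            seed_regions = list(config.plsr_seed_regions)
        elif spec is not None and spec.lost_edges_het:
            seed_regions = sorted({e[0] for e in spec.lost_edges_het})
        else:
            seed_regions = [0]
        wt_sal, het_sal = config.network_groups[:2]
        groups = [wt_sal, het_sal, config.drug_group]
        change_rows = []
        restored_rows = []
        for sr in seed_regions:
            tables = {}
            for g in groups:
                t = plsr.vip_jackknife(cohort, g, sr, config.n_components)
                tables[g] = t
                pd.DataFrame(
                    {
                        "target": [cohort.regions.abbreviation[j] for j in t.targets],
                        "vip": t.vip,
                        "se": t.se,
                        "ci_lower": t.ci_lower,
                        "ci_upper": t.ci_upper,
                        "significant": t.significant,
                    }
                ).to_csv(
                    sdir
                    / f"vip_{'_'.join(g)}_seed_{cohort.regions.abbreviation[sr]}.csv",
                    index=False,
                )
            changes = plsr.classify_changes(
                tables[wt_sal], tables[het_sal], config.alpha
            )
            for c in changes:
                change_rows.append(
                    {
                        "seed": cohort.regions.abbreviation[c.seed],
                        "target": cohort.regions.abbreviation[c.target],
                        "label": c.label,
                        "p_adjusted": c.p_adjusted,
                    }
                )
            for c in plsr.classify_restoration(
                tables[het_sal], tables[config.drug_group], tables[wt_sal], config.alpha
            ):
                restored_rows.append(
                    {
                        "seed": cohort.regions.abbreviation[c.seed],
                        "target": cohort.regions.abbreviation[c.target],
                        "p_adjusted": c.p_adjusted,
                    }
                )
        pd.DataFrame(
            change_rows, columns=["seed", "target", "label", "p_adjusted"]
        ).to_csv(sdir / "connectivity_changes.csv", index=False)
        pd.DataFrame(
            restored_rows, columns=["seed", "target", "p_adjusted"]
        ).to_csv(sdir / "restored.csv", index=False)
        summary["connectivity"] = {
            "lost": [
                (r["seed"], r["target"]) for r in change_rows if r["label"] == "lost"
            ],
            "gained": [
                (r["seed"], r["target"]) for r in change_rows if r["label"] == "gained"
            ],
            "restored": [(r["seed"], r["target"]) for r in restored_rows],
        }
        log(stage, seed=None, n_seeds=len(seed_regions))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
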