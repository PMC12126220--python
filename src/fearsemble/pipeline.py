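"""End-to-end runner: simulate two treatment groups, analyse, write a manifest.

The pipeline wires the stages in dependency order on synthetic sessions:
generate vehicle and treated ensembles, build peri-tone z tensors,
classify the 9-type taxonomy per group, compare dual-responsive
proportions, compute preference indices and their KS comparison, cluster
the concatenated responses, and quantify trajectory geometry.  Every
stochastic step takes a named seed from the config; outputs and a digest
manifest land in a run directory so reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import align, cluster, popgeo, prefer, respond, synthdata
from .io import EventType

REQUIRED_SEEDS = ("vehicle", "treated", "match")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    seeds = cfg.get("seeds")
    if not isinstance(seeds, dict):
        raise ConfigError("config missing 'seeds' block")
    for name in REQUIRED_SEEDS:
        if name not in seeds:
            raise ConfigError(f"config missing seed: seeds.{name}")
        if not isinstance(seeds[name], int):
            raise ConfigError(f"seeds.{name} must be an integer")


def default_config() -> dict:
    return {
        "session": {"n_nt_tones": 4, "n_cs_tones": 4},
        "population": {
            "vehicle": {
                "n_neurons": 200,
                "archetype_fractions": {
                    "nt_plus": 0.05,
                    "cs_plus": 0.20,
                    "dual_plus": 0.05,
                    "cs_minus": 0.05,
                    "none": 0.65,
                },
            },
            "treated": {
                "n_neurons": 220,
                "archetype_fractions": {
                    "nt_plus": 0.05,
                    "cs_plus": 0.12,
                    "dual_plus": 0.15,
                    "cs_minus": 0.05,
                    "none": 0.63,
                },
            },
        },
        "cluster": {"frac": 0.05},
        "popgeo": {"k": 15},
        "seeds": {"vehicle": 11, "treated": 12, "match": 13},
    }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyse_group(pop_cfg: dict, sess: synthdata.SessionSpec, seed: int) -> dict:
    pop = synthdata.PopulationSpec(seed=seed, **pop_cfg)
    traces, schedule, truth = synthdata.generate_session(pop, sess)
    tensors = {
        tt: align.peri_tone_tensor(traces, schedule, tt)
        for tt in (EventType.NT, EventType.CS_PLUS)
    }
    labels = {tt: respond.classify_tensor(tensors[tt]) for tt in tensors}
    taxonomy = respond.response_taxonomy(
        labels[EventType.NT], labels[EventType.CS_PLUS], traces.neuron_ids
    )
    z_nt, _ = align.ztransform_whole_session(traces, schedule, EventType.NT)
    z_cs, _ = align.ztransform_whole_session(traces, schedule, EventType.CS_PLUS)
    return {
        "traces": traces,
        "schedule": schedule,
        "truth": truth,
        "tensors": tensors,
        "taxonomy": taxonomy,
        "proportions": respond.taxonomy_proportions(taxonomy),
        "preference": prefer.preference_table(z_nt, z_cs, traces.neuron_ids),
    }


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute all stages; write CSV/JSON outputs and a digest manifest."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sess = synthdata.SessionSpec(**cfg.get("session", {}))
    seeds = cfg["seeds"]

    groups = {}
    for name in ("vehicle", "treated"):
        try:
            groups[name] = _analyse_group(cfg["population"][name], sess, seeds[name])
        except Exception as e:
            raise RuntimeError(f"stage group-analysis[{name}] failed: {e}") from e

    veh, trt = groups["vehicle"], groups["treated"]
    fisher = respond.compare_type_proportions(
        veh["proportions"], trt["proportions"], "dual"
    )
    ks = prefer.preference_distribution_compare(
        veh["preference"]["preference"], trt["preference"]["preference"]
    )

    # clustering on the vehicle group's concatenated NT/CS+ mean block traces
    def mean_tone_traces(g):
        nt = g["tensors"][EventType.NT].tone_z().mean(axis=1)
        cs = g["tensors"][EventType.CS_PLUS].tone_z().mean(axis=1)
        return nt, cs

    nt_v, cs_v = mean_tone_traces(veh)
    concat_v = np.hstack([nt_v, cs_v])
    rescaled = cluster.rescale_bounded(concat_v)
    linkage = cluster.ward_cluster(rescaled)
    clusters = cluster.cut_and_remap(
        linkage,
        rescaled,
        concat_v,
        frac=cfg.get("cluster", {}).get("frac", 0.05),
        neuron_ids=list(veh["taxonomy"]["neuron_id"]),
    )

    nt_t, cs_t = mean_tone_traces(trt)
    pop_matrix = popgeo.build_population_matrix(
        nt_v, cs_v, nt_t, cs_t, match_seed=seeds["match"]
    )
    k = min(cfg.get("popgeo", {}).get("k", 15), *pop_matrix.values.shape)
    trajs = popgeo.pca_reduce(pop_matrix, k=k)
    geometry = {}
    for name in ("vehicle", "treated"):
        sep = popgeo.mahalanobis_separation(trajs[(name, "NT")], trajs[(name, "CS_PLUS")])
        eud = popgeo.euclidean_trajectory_distance(
            trajs[(name, "NT")], trajs[(name, "CS_PLUS")], k=k
        )
        geometry[name] = {
            "mahalanobis_mean": sep["mean"],
            "mahalanobis": sep["distances"].tolist(),
            "euclidean": eud.tolist(),
        }
    geometry["t_test"] = popgeo.compare_separation(
        np.array(geometry["vehicle"]["mahalanobis"]),
        np.array(geometry["treated"]["mahalanobis"]),
    )
    var = trajs[("vehicle", "NT")].variance_explained
    geometry["variance_explained_k"] = float(var[:k].sum())

    # ---- outputs ----
    files: list[Path] = []
    for name, g in groups.items():
        p = out / f"taxonomy_{name}.csv"
        g["taxonomy"].to_csv(p, index=False)
        files.append(p)
        p = out / f"preference_{name}.csv"
        g["preference"].to_csv(p, index=False, float_format="%.10g")
        files.append(p)
    p = out / "clusters.csv"
    clusters.assignments.to_csv(p)
    files.append(p)
    p = out / "linkage.csv"
    cluster.write_linkage(linkage, p)
    files.append(p)
    summary = {
        "config": cfg,
        "n_neurons": {n: int(len(g["taxonomy"])) for n, g in groups.items()},
        "dual_proportion": {
            n: g["proportions"]["dual_proportion"] for n, g in groups.items()
        },
        "fisher_dual": fisher,
        "ks_preference": ks,
        "n_clusters": clusters.n_clusters,
        "geometry": geometry,
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(p)

    manifest = {
        "parameters": cfg,
        "seeds": seeds,
        "outputs": {f.name: _digest(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary


def write_default_config(path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(default_config(), f, sort_keys=False)
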