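"""Full-pipeline orchestration: simulate -> score -> cluster -> paths -> report.

``run_pipeline`` chains the synthetic compartment dataset through synapse
similarity and clustering, and the synthetic reflex connectome through
thresholded path enumeration and layer assignment, writing a deterministic
JSON report plus CSV/Newick/GraphML artifacts. Every parameter is validated
against module preconditions before any computation; any stage failure
removes partial outputs and raises PipelineError naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .clustering import (average_linkage, compartment_composition,
                         cut_dendrogram, similarity_to_distance)
from .errors import ConfigError, PipelineError
from .io import (write_annotations_csv, write_bundle, write_dendrogram_newick,
                 write_graph_csv, write_matrix_csv, write_paths_graphml)
from .model import build_graph
from .paths import (PathQuery, assign_layers, convergence_divergence,
                    enumerate_paths)
from .simulate import (CircuitSpec, CompartmentSpec,
                       generate_compartment_dataset, generate_reflex_connectome)
from .synapses import SynapseSimParams, clouds_from_connectors, synapse_similarity_matrix

DEFAULT_CONFIG = {
    "seed": 42,
    "sigma_nm": 2000.0,
    "omega_nm": 2000.0,
    "sigma_morph_nm": 2000.0,
    "c1": 0.5,
    "c2": 1.0,
    "score_cut": 0.06,
    "threshold": 2,
    "compartments": {
        "k": 7,
        "centroid_sep_nm": 20000.0,
        "spread_nm": 1000.0,
        "neurons_per_cluster": 5,
        "synapses_per_neuron": [10, 20],
    },
    "circuit": {
        "n_sensory": 12,
        "n_inter": 15,
        "n_output": 3,
        "p_mono": 0.25,
        "p_l2": 0.20,
        "p_l3": 0.12,
        "p_sensory_inter": 0.25,
    },
}


def load_config(path=None, overrides=None) -> dict:
    """Merge defaults <- YAML file <- overrides, then validate."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        _merge(cfg, loaded)
    if overrides:
        _merge(cfg, {k: v for k, v in overrides.items() if v is not None})
    validate_config(cfg)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def validate_config(cfg: dict) -> None:
    """Check every parameter against module preconditions before computing."""
    if cfg["sigma_nm"] <= 0 or cfg["omega_nm"] <= 0 or cfg["sigma_morph_nm"] <= 0:
        raise ConfigError("sigma/omega must be > 0")
    if not 0.0 <= cfg["c1"] <= 1.0 or cfg["c2"] < 0:
        raise ConfigError("C1 must lie in [0,1] and C2 >= 0")
    if not 0.0 <= cfg["score_cut"] <= 1.0:
        raise ConfigError("score_cut must lie in [0, 1]")
    if cfg["threshold"] < 1:
        raise ConfigError("threshold must be >= 1")
    comp = cfg["compartments"]
    if comp["k"] < 1 or comp["spread_nm"] <= 0 or comp["centroid_sep_nm"] <= 0:
        raise ConfigError("invalid compartment spec")
    circ = cfg["circuit"]
    for p in ("p_mono", "p_l2", "p_l3", "p_sensory_inter"):
        if not 0.0 <= circ[p] <= 1.0:
            raise ConfigError(f"{p} must lie in [0, 1]")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full simulate/score/cluster/paths pipeline; returns the report.

    Deterministic given the config (including its seed): rerunning with the
    same config produces byte-identical report files.
    """
    validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []

    def track(path):
        written.append(Path(path))
        return path

    report = {
        "package": "sezconn",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "stages": {},
    }
    stage = "init"
    try:
        # -- compartments: simulate, score, cluster -------------------------
        stage = "simulate-compartments"
        comp_cfg = config["compartments"]
        comp_spec = CompartmentSpec(
            k=comp_cfg["k"],
            centroid_sep_nm=comp_cfg["centroid_sep_nm"],
            spread_nm=comp_cfg["spread_nm"],
            neurons_per_cluster=comp_cfg["neurons_per_cluster"],
            synapses_per_neuron=tuple(comp_cfg["synapses_per_neuron"]),
        )
        comp_bundle, planted = generate_compartment_dataset(comp_spec, config["seed"])
        comp_dir = out / "compartments"
        for p in write_bundle(comp_bundle, comp_dir).values():
            track(p)

        stage = "synapse-similarity"
        sensory_ids = [
            nid for nid, cls in comp_bundle.annotations["class"].items()
            if cls == "sensory"
        ]
        clouds = clouds_from_connectors(comp_bundle.connectors, neuron_ids=sensory_ids)
        params = SynapseSimParams(sigma=config["sigma_nm"], omega=config["omega_nm"])
        matrix = synapse_similarity_matrix(clouds, params, symmetrize=True)
        write_matrix_csv(track(comp_dir / "synapse_similarity.csv"), matrix)

        stage = "cluster"
        labels, dist = similarity_to_distance(matrix)
        dendrogram = average_linkage(dist, labels)
        (comp_dir / "dendrogram.nwk").write_text(
            write_dendrogram_newick(dendrogram) + "\n", encoding="utf-8"
        )
        track(comp_dir / "dendrogram.nwk")
        assignment = cut_dendrogram(dendrogram, config["score_cut"])
        with open(track(comp_dir / "clusters.csv"), "w", encoding="utf-8") as fh:
            fh.write("neuron_id,cluster\n")
            for nid in sorted(assignment.mapping, key=str):
                fh.write(f"{nid},{assignment.mapping[nid]}\n")
        composition = compartment_composition(
            assignment, comp_bundle.annotations, by="origin"
        )
        composition.to_csv(track(comp_dir / "composition_by_origin.csv"))
        sizes = {str(k): len(v) for k, v in assignment.members().items()}
        recovered = _recovery(assignment.mapping, planted)
        report["stages"]["compartments"] = {
            "n_neurons": len(sensory_ids),
            "n_clusters": assignment.n_clusters,
            "planted_k": comp_spec.k,
            "cluster_sizes": sizes,
            "planted_partition_recovered": recovered,
        }

        # -- circuit: simulate, graph, paths, layers ------------------------
        stage = "simulate-circuit"
        circ_cfg = config["circuit"]
        circ_spec = CircuitSpec(
            n_sensory=circ_cfg["n_sensory"],
            n_inter=circ_cfg["n_inter"],
            n_output=circ_cfg["n_output"],
            p_mono=circ_cfg["p_mono"],
            p_l2=circ_cfg["p_l2"],
            p_l3=circ_cfg["p_l3"],
            p_sensory_inter=circ_cfg["p_sensory_inter"],
            threshold=config["threshold"],
            seed=config["seed"] + 1,
        )
        circ_bundle, truth = generate_reflex_connectome(circ_spec)
        circ_dir = out / "circuit"
        for p in write_bundle(circ_bundle, circ_dir).values():
            track(p)

        stage = "paths"
        graph = build_graph(circ_bundle.connectors)
        write_graph_csv(track(circ_dir / "graph.csv"), graph)
        ann = circ_bundle.annotations
        sensory = sorted(ann.index[ann["class"] == "sensory"])
        outputs = sorted(
            ann.index[ann["class"].isin(["motor", "neurosecretory", "serotonergic"])]
        )
        per_output = {}
        for o in outputs:
            query = PathQuery(frozenset(sensory), o, threshold=config["threshold"])
            pathset = enumerate_paths(graph, query, ann)
            layers = assign_layers(graph, sensory, o, config["threshold"], ann)
            conv = convergence_divergence(pathset)
            write_paths_graphml(
                pathset, track(circ_dir / f"paths_{o}.graphml"),
                annotations=ann, layers=layers,
            )
            per_output[str(o)] = {
                "n_paths": {str(h): len(pathset.by_hops(h)) for h in (1, 2, 3)},
                "layers": {
                    lab: sorted(str(n) for n in layers.members(lab))
                    for lab in ("L1-source", "L2", "L3a", "L3b")
                },
                "max_convergence_degree": max(conv.degree.values(), default=0),
                "max_divergence": max(conv.divergence.values(), default=0),
                "matches_planted_inventory": _paths_match(pathset, truth, o),
            }
        report["stages"]["circuit"] = {
            "n_edges": sum(1 for _ in graph.edges()),
            "total_synaptic_connections": graph.total_weight(),
            "per_output": per_output,
        }

        stage = "report"
        report_path = out / "report.json"
        report_path.write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
    except Exception as exc:  # noqa: BLE001 - abort cleanly, name the stage
        for p in written:
            try:
                if p.is_file():
                    p.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return report


def _recovery(mapping: dict, planted: dict) -> bool:
    """True iff the flat clustering equals the planted partition (as set of sets)."""
    found: dict = {}
    for nid, lab in mapping.items():
        found.setdefault(lab, set()).add(nid)
    want: dict = {}
    for nid, lab in planted.items():
        want.setdefault(lab, set()).add(nid)
    return set(map(frozenset, found.values())) == set(map(frozenset, want.values()))


def _paths_match(pathset, truth, output) -> bool:
    got = {h: {p.nodes for p in pathset.by_hops(h)} for h in (1, 2, 3)}
    want = truth["per_output"][output]["paths"]
    return all(got[h] == want[h] for h in (1, 2, 3))
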