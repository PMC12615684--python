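"""HDF5 persistence for simulated ensembles."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .racipe_ensemble import (ClusterResult, Ensemble, EnsembleConfig,
                              RacipeModel, RacipeParams, Transform)
from .topology import Topology

__all__ = ["save_ensemble", "load_ensemble"]


def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_models"] = len(ensemble.models)
        topo = f.create_group("topology")
        topo.create_dataset("nodes", data=np.array(ensemble.topology.nodes, dtype="S"))
        src, tgt, sgn = ensemble.topology.edge_arrays()
        topo.create_dataset("src", data=src)
        topo.create_dataset("tgt", data=tgt)
        topo.create_dataset("sign", data=sgn)
        cfg = f.create_group("config")
        for k, v in vars(ensemble.config).items():
            cfg.attrs[k] = v
        f.create_dataset("pooled_states", data=ensemble.pooled_states)
        f.create_dataset("processed", data=ensemble.processed)
        tf = f.create_group("transform")
        tf.create_dataset("mean", data=ensemble.transform.mean)
        tf.create_dataset("sd", data=ensemble.transform.sd)
        cl = f.create_group("clustering")
        cl.create_dataset("labels", data=np.array(ensemble.clustering.labels, dtype="S"))
        cl.attrs["k_selected"] = ensemble.clustering.k_selected
        for kk, v in ensemble.clustering.silhouette_by_k.items():
            cl.attrs[f"silhouette_k{kk}"] = v
        mg = f.create_group("models")
        for m in ensemble.models:
            g = mg.create_group(str(m.model_id))
            g.attrs["n_unconverged"] = m.n_unconverged
            g.create_dataset("G", data=m.params.G)
            g.create_dataset("k", data=m.params.k)
            g.create_dataset("lam", data=m.params.lam)
            g.create_dataset("thr", data=m.params.thr)
            g.create_dataset("hill", data=m.params.hill)
            if m.steady_states:
                g.create_dataset("states", data=np.stack(m.steady_states))
            g.create_dataset("labels", data=np.array(m.labels, dtype="S"))


def load_ensemble(path: str | Path) -> Ensemble:
    with h5py.File(path, "r") as f:
        nodes = tuple(n.decode() for n in f["topology/nodes"][:])
        src = f["topology/src"][:]
        tgt = f["topology/tgt"][:]
        sgn = f["topology/sign"][:]
        edges = tuple((nodes[s], nodes[t], int(w)) for s, t, w in zip(src, tgt, sgn))
        topology = Topology(nodes=nodes, edges=edges)
        cfg_attrs = dict(f["config"].attrs)
        fields = {}
        for k, v in cfg_attrs.items():
            if isinstance(v, bytes):
                v = v.decode()
            elif isinstance(v, np.ndarray):
                v = tuple(v.tolist())
            elif isinstance(v, np.generic):
                v = v.item()
            fields[k] = v
        config = EnsembleConfig(**fields)
        transform = Transform(mean=f["transform/mean"][:], sd=f["transform/sd"][:])
        clustering = ClusterResult(
            labels=np.array([b.decode() for b in f["clustering/labels"][:]]),
            k_selected=int(f["clustering"].attrs["k_selected"]),
            silhouette_by_k={int(k[len("silhouette_k"):]): float(v)
                             for k, v in f["clustering"].attrs.items()
                             if k.startswith("silhouette_k")},
        )
        models = []
        mg = f["models"]
        for mid in sorted(mg, key=int):
            g = mg[mid]
            params = RacipeParams(G=g["G"][:], k=g["k"][:], lam=g["lam"][:],
                                  thr=g["thr"][:], hill=g["hill"][:])
            states = [row for row in g["states"][:]] if "states" in g else []
            labels = [b.decode() for b in g["labels"][:]]
            models.append(RacipeModel(model_id=int(mid), params=params,
                                      steady_states=states, labels=labels,
                                      n_unconverged=int(g.attrs["n_unconverged"])))
        return Ensemble(topology=topology, config=config, models=models,
                        pooled_states=f["pooled_states"][:],
                        processed=f["processed"][:], transform=transform,
                        clustering=clustering)
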