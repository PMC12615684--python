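"""Loaders for user-supplied network inputs.

The published 26-node/100-edge EMT network and its epithelial/mesenchymal
score table are distributed in the original authors' code repository
(https://github.com/dan-ramirez-23/EMT_Transitions_2025, `inputs/`), not
with this package.  Drop the files into a local data directory to run the
full-network reproductions; everything else in the package works on the
synthetic fixtures.
"""

from __future__ import annotations

from pathlib import Path

from .topology import NodeAnnotation, Topology, read_annotation, read_topo

__all__ = ["load_emt_network", "EMT_TOPO_FILENAME", "EMT_SCORES_FILENAME"]

EMT_TOPO_FILENAME = "emt26.topo"
EMT_SCORES_FILENAME = "emt26_scores.tsv"


def load_emt_network(data_dir: str | Path = "data") -> tuple[Topology, NodeAnnotation]:
    """Load the user-supplied 26-node EMT topology and E/M score table.

    Expects ``<data_dir>/emt26.topo`` (Source Target Type; 1=activation,
    2=inhibition) and ``<data_dir>/emt26_scores.tsv`` (gene score, score in
    {-1, 0, 1}).  Raises FileNotFoundError with provenance guidance if the
    files are absent.
    """
    data_dir = Path(data_dir)
    topo_path = data_dir / EMT_TOPO_FILENAME
    score_path = data_dir / EMT_SCORES_FILENAME
    if not topo_path.exists() or not score_path.exists():
        raise FileNotFoundError(
            f"EMT network inputs not found ({topo_path}, {score_path}). "
            "These files are distributed in the original authors' repository "
            "(github.com/dan-ramirez-23/EMT_Transitions_2025, inputs/); copy "
            "them to the data directory to enable full-network runs."
        )
    return read_topo(topo_path), read_annotation(score_path)
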