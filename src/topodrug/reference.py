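"""Packaged input data and published reference tables.

``drug_graphs`` loads the ten anti-arrhythmia fixture graphs;
``property_table`` the physicochemical property table (density D, boiling
point BP in deg C, flash point FP in deg C, bioconcentration factor BCF,
organic-carbon partition coefficient KOC, polarizability P, molar volume
MV in cm^3).  The ``published_*`` loaders return the tables of the source
study that the pipeline reproduces; they serve as regression baselines and
as the documented divergence record, never as computation inputs except
where noted (the published decision matrix and index table are legitimate
pipeline inputs, because the study's own downstream analysis starts from
them).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .molgraph import MolecularGraph, load_graph

__all__ = [
    "DRUGS",
    "drug_graph_paths",
    "drug_graphs",
    "property_table",
    "published_indices",
    "published_decision_matrix",
    "published_weights",
    "published_weighted_matrix",
    "published_ideals",
    "published_topsis",
    "published_saw_normalized",
    "published_saw_weighted",
    "published_saw_scores",
    "published_correlations",
    "published_regressions",
    "published_polynomials",
]

DRUGS = (
    "metoprolol",
    "atenolol",
    "bisoprolol",
    "propranolol",
    "sotalol",
    "amiodarone",
    "carvedilol",
    "flecainide",
    "propafenone",
    "timolol",
)


def _data_dir() -> Path:
    return Path(str(resources.files("topodrug") / "data"))


def drug_graph_paths() -> dict[str, Path]:
    """Map drug name -> fixture edge-list path.

    Index-matched synthetic reconstructions (used where the published
    polynomial is not realizable as a graph) carry a ``.synthetic``
    marker in the file name and are preferred over a plain file of the
    same drug if both exist.
    """
    gdir = _data_dir() / "graphs"
    out: dict[str, Path] = {}
    for drug in DRUGS:
        synthetic = gdir / f"{drug}.synthetic.edgelist"
        plain = gdir / f"{drug}.edgelist"
        if synthetic.exists():
            out[drug] = synthetic
        elif plain.exists():
            out[drug] = plain
        else:
            raise FileNotFoundError(f"missing fixture graph for {drug!r}: {plain}")
    return out


def drug_graphs() -> dict[str, MolecularGraph]:
    """The ten fixture graphs, keyed and ordered by drug name."""
    return {drug: load_graph(path) for drug, path in drug_graph_paths().items()}


def _load_csv(rel: str, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(_data_dir() / rel, index_col=index_col)


def property_table() -> pd.DataFrame:
    return _load_csv("properties.csv")


def published_indices() -> pd.DataFrame:
    return _load_csv("published/indices.csv")


def published_decision_matrix() -> pd.DataFrame:
    return _load_csv("published/decision_matrix.csv")


def published_weights() -> pd.Series:
    return _load_csv("published/weights.csv")["weight"]


def published_weighted_matrix() -> pd.DataFrame:
    return _load_csv("published/weighted_matrix.csv")


def published_ideals() -> pd.DataFrame:
    return _load_csv("published/ideals.csv")


def published_topsis() -> pd.DataFrame:
    return _load_csv("published/topsis.csv")


def published_saw_normalized() -> pd.DataFrame:
    return _load_csv("published/saw_normalized.csv")


def published_saw_weighted() -> pd.DataFrame:
    return _load_csv("published/saw_weighted.csv")


def published_saw_scores() -> pd.DataFrame:
    return _load_csv("published/saw_scores.csv")


def published_correlations() -> pd.DataFrame:
    return _load_csv("published/correlations.csv")


def published_regressions() -> pd.DataFrame:
    return _load_csv("published/regressions.csv", index_col=[0, 1])


#: Neighborhood-polynomial edge partitions exactly as printed in the source
#: study (one generating polynomial per drug).  The carvedilol entry is
#: internally inconsistent with the published index table (it sums to 31
#: edges and implies NM1=333, NM2=925 against the published 360/1029) and
#: the atenolol, sotalol and flecainide entries are not realizable by any
#: simple connected graph together with their published M1/M2 — all four
#: are retained verbatim as the divergence record.
PUBLISHED_POLYNOMIALS: dict[str, dict[tuple[int, int], int]] = {
    "metoprolol": {(2, 3): 1, (3, 4): 3, (3, 5): 1, (4, 5): 2, (5, 5): 6, (5, 6): 6},
    "propranolol": {(3, 4): 2, (4, 4): 1, (4, 5): 5, (3, 5): 1, (5, 5): 4, (5, 7): 4, (5, 8): 1, (7, 8): 2},
    "atenolol": {(2, 3): 1, (3, 4): 2, (3, 5): 2, (4, 6): 1, (5, 5): 5, (5, 6): 5, (6, 6): 1},
    "bisoprolol": {(3, 4): 4, (3, 5): 1, (4, 4): 2, (4, 5): 4, (5, 5): 6, (5, 6): 6},
    "sotalol": {(3, 4): 2, (3, 5): 1, (4, 5): 4, (5, 5): 4, (5, 6): 2, (5, 7): 4, (6, 7): 1},
    "amiodarone": {
        (2, 3): 1, (2, 4): 2, (3, 4): 1, (3, 6): 2, (3, 7): 1, (4, 4): 1, (4, 5): 5, (4, 6): 2,
        (5, 6): 1, (5, 7): 2, (5, 8): 2, (6, 6): 2, (6, 7): 4, (6, 8): 2, (7, 7): 1, (7, 8): 1,
        (7, 9): 2, (8, 9): 1,
    },
    "carvedilol": {
        (2, 4): 1, (4, 4): 4, (4, 5): 8, (4, 7): 1, (3, 5): 1, (5, 7): 7, (5, 5): 2, (5, 8): 1,
        (6, 7): 2, (7, 7): 1, (7, 8): 1, (7, 9): 2,
    },
    "flecainide": {
        (3, 6): 1, (4, 4): 2, (4, 5): 8, (5, 5): 5, (5, 6): 7, (5, 7): 2, (6, 6): 1, (6, 8): 2, (7, 8): 1,
    },
    "timolol": {(3, 5): 1, (4, 4): 2, (4, 5): 7, (5, 5): 3, (5, 6): 2, (5, 7): 4, (5, 8): 1, (7, 8): 2},
    "propafenone": {
        (2, 3): 1, (3, 4): 1, (3, 5): 1, (3, 6): 1, (4, 4): 4, (4, 5): 5, (5, 5): 4, (5, 6): 4,
        (5, 7): 2, (5, 8): 1, (6, 8): 1, (7, 8): 1,
    },
}


def published_polynomials() -> dict[str, dict[tuple[int, int], int]]:
    return {k: dict(v) for k, v in PUBLISHED_POLYNOMIALS.items()}
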