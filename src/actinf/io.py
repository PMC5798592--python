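"""Serialization: model documents (YAML/JSON + optional HDF5 arrays),
trial records (HDF5 + JSON metadata) and CSV trace exports."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .discrete_model import DiscreteModel


def model_to_dict(model: DiscreteModel, inline_arrays: bool = True) -> dict:
    """Plain-document form of a model; field names mirror the conventional
    symbols (A, B, C, D, policies, T)."""
    doc = {
        "T": int(model.T),
        "control_factors": list(model.control_factors),
    }
    if inline_arrays:
        doc.update({
            "A": [a.tolist() for a in model.A],
            "B": [b.tolist() for b in model.B],
            "C": [c.tolist() for c in model.C],
            "D": [d.tolist() for d in model.D],
            "policies": model.policies.tolist(),
        })
    return doc


def model_from_dict(doc: dict) -> DiscreteModel:
    return DiscreteModel(
        A=[np.asarray(a, dtype=float) for a in doc["A"]],
        B=[np.asarray(b, dtype=float) for b in doc["B"]],
        C=[np.asarray(c, dtype=float) for c in doc.get("C", [])] or None,
        D=[np.asarray(d, dtype=float) for d in doc["D"]],
        policies=np.asarray(doc["policies"], dtype=int),
        T=int(doc["T"]),
        control_factors=tuple(doc.get("control_factors", ())),
    )


def save_model(model: DiscreteModel, path, arrays_h5: bool = False) -> None:
    """Write a model document.  ``.yaml``/``.yml`` and ``.json`` are chosen
    by suffix; with ``arrays_h5=True`` the arrays go to a ``.h5`` side file
    and the document stores only shapes and the reference."""
    path = Path(path)
    doc = model_to_dict(model, inline_arrays=not arrays_h5)
    if arrays_h5:
        import h5py

        h5path = path.with_suffix(".h5")
        with h5py.File(h5path, "w") as f:
            for name, arrs in (("A", model.A), ("B", model.B),
                               ("C", model.C), ("D", model.D)):
                grp = f.create_group(name)
                for i, a in enumerate(arrs):
                    grp.create_dataset(str(i), data=a)
            f.create_dataset("policies", data=model.policies)
        doc["arrays"] = h5path.name
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc))


def load_model(path) -> DiscreteModel:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(path.read_text())
    else:
        doc = json.loads(path.read_text())
    if "arrays" in doc:
        import h5py

        with h5py.File(path.parent / doc["arrays"], "r") as f:
            for name in ("A", "B", "C", "D"):
                doc[name] = [f[name][str(i)][()]
                             for i in range(len(f[name]))]
            doc["policies"] = f["policies"][()]
    return model_from_dict(doc)


def save_trial_record(rec, path) -> None:
    """Trial record to HDF5 (arrays) plus an embedded JSON metadata blob."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = {
            "n_epochs": len(rec.outcomes),
            "outcomes": [list(map(int, o)) for o in rec.outcomes],
            "actions": [list(map(int, a)) for a in rec.actions],
            "true_states": [list(map(int, s)) if s is not None else None
                            for s in rec.true_states],
        }
        f.attrs["meta"] = json.dumps(meta)
        for t, belief in enumerate(rec.beliefs):
            grp = f.create_group(f"epoch_{t}")
            grp.create_dataset("pi", data=belief.pi)
            grp.create_dataset("G", data=belief.G)
            if belief.F is not None:
                grp.create_dataset("F", data=belief.F)
            for fct, bma in enumerate(belief.bma):
                grp.create_dataset(f"bma_{fct}", data=bma)


def export_traces_csv(rec, path) -> None:
    """Per-epoch pi, G and final-iteration F to a tidy CSV for plotting."""
    import pandas as pd

    rows = []
    for t, belief in enumerate(rec.beliefs):
        for p in range(len(belief.pi)):
            rows.append({
                "epoch": t, "policy": p,
                "pi": float(belief.pi[p]),
                "G": float(belief.G[p]),
                "F": float(belief.F[p, -1]) if belief.F is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
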