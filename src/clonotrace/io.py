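"""Plain-text readers/writers for the pipeline's tables.

Everything on disk is TSV or JSON (FASTQ is handled in ``extract``), so every
stage's inputs and outputs are diffable."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .models import ConstructDefinition, PoolModel

WHITELIST_COLUMNS = ["construct_id", "gene_symbol", "perturbation_class", "barcode5", "barcode3"]


def write_whitelist(pool: PoolModel, path, titer_path=None) -> None:
    rows = [
        {
            "construct_id": c.construct_id,
            "gene_symbol": c.gene_symbol,
            "perturbation_class": c.perturbation_class,
            "barcode5": c.barcode5,
            "barcode3": c.barcode3,
        }
        for c in pool.constructs
    ]
    pd.DataFrame(rows, columns=WHITELIST_COLUMNS).to_csv(path, sep="\t", index=False)
    if titer_path is not None:
        pd.DataFrame(
            {"construct_id": pool.construct_ids, "titer_weight": pool.titer_weights}
        ).to_csv(titer_path, sep="\t", index=False)


def read_whitelist(path, titer_path=None) -> PoolModel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(WHITELIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"whitelist is missing columns {sorted(missing)}")
    constructs = [
        ConstructDefinition(
            r["construct_id"], r["gene_symbol"], r["perturbation_class"], r["barcode5"], r["barcode3"]
        )
        for r in df.to_dict("records")
    ]
    if titer_path is not None:
        t = pd.read_csv(titer_path, sep="\t").set_index("construct_id")["titer_weight"]
        weights = t.reindex([c.construct_id for c in constructs]).to_numpy(dtype=float)
    else:
        weights = np.full(len(constructs), 1.0 / len(constructs))
    return PoolModel(constructs, weights / weights.sum())


def write_cell_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_region_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_region_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "histology": str, "construct_id": str})
    df["count"] = df["count"].astype(int)
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
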