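"""Plain-text file formats and atomic writing.

The universal exchange object is the count-matrix TSV: a header row of
sample names, a first column of entity identifiers, and integer cells.
Conditions travel in a two-column sidecar (<path>.conditions.tsv), and
simulation ground truth in a truth sidecar (<path>.truth.tsv).  All writes
are atomic (write to a temporary file, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .generators import CountMatrix
from .normalization import NormalizationFactors
from .profiles import AbundanceProfile, PerturbedPair

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_profile",
    "write_profile",
    "write_factors",
    "write_results",
    "write_json",
    "atomic_write",
]


def atomic_write(path, text: str) -> None:
    """Write text to ``path`` via a temporary file and rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sidecar(path, kind: str) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + f".{kind}.tsv")


def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Write the count TSV plus condition and (if present) truth sidecars."""
    df = matrix.to_frame()
    atomic_write(path, df.to_csv(sep="\t", index_label="entity_id"))
    cond = pd.DataFrame({"sample_id": matrix.sample_ids, "condition": matrix.condition})
    atomic_write(_sidecar(path, "conditions"), cond.to_csv(sep="\t", index=False))
    if matrix.truth is not None:
        t = matrix.truth
        truth = pd.DataFrame(
            {"entity_id": t.entity_ids, "label": t.da_label, "fold_change": t.fc}
        )
        atomic_write(_sidecar(path, "truth"), truth.to_csv(sep="\t", index=False))


def read_count_matrix(path) -> CountMatrix:
    """Read a count TSV; honors condition/truth sidecars when present.

    Rejects duplicate entity identifiers and non-integer or negative cells,
    naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate entity ID {dup!r}")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) % 1 != 0) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative count at entity {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    cond_path = _sidecar(path, "conditions")
    if cond_path.exists():
        cond_df = pd.read_csv(cond_path, sep="\t").set_index("sample_id")
        condition = cond_df.loc[list(df.columns), "condition"].to_numpy()
    else:
        condition = np.ones(df.shape[1], dtype=int)
    truth = None
    truth_path = _sidecar(path, "truth")
    if truth_path.exists():
        # keep_default_na: the label "null" is data, not a missing value
        t = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
        fc = t["fold_change"].to_numpy(dtype=float)
        root = np.sqrt(fc)
        base = np.ones(len(t)) / len(t)
        m1, m2 = base / root, base * root
        truth = PerturbedPair(
            mean1=m1 / m1.sum(),
            mean2=m2 / m2.sum(),
            da_label=t["label"].to_numpy(dtype=object),
            fc=fc,
            entity_ids=list(t["entity_id"].astype(str)),
        )
    return CountMatrix(
        counts=values.astype(np.int64),
        entity_ids=[str(e) for e in df.index],
        sample_ids=[str(s) for s in df.columns],
        condition=condition,
        truth=truth,
    )


def write_profile(profile: AbundanceProfile, path) -> None:
    """Two-column TSV (entity_id, relative_abundance) at 12 significant digits."""
    lines = ["entity_id\trelative_abundance"]
    lines += [
        f"{e}\t{a:.12g}" for e, a in zip(profile.entity_ids, profile.abundances)
    ]
    atomic_write(path, "\n".join(lines) + "\n")


def read_profile(path) -> AbundanceProfile:
    df = pd.read_csv(path, sep="\t")
    return AbundanceProfile(
        df["relative_abundance"].to_numpy(dtype=float),
        entity_ids=list(df["entity_id"].astype(str)),
    )


def write_factors(factors: NormalizationFactors, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": factors.sample_ids,
            "factor": factors.factors,
            "method": factors.method,
        }
    )
    atomic_write(path, df.to_csv(sep="\t", index=False))
    atomic_write(Path(path).with_suffix(".flags.json"), json.dumps(factors.flags, indent=2))


def write_results(result, path) -> None:
    atomic_write(path, result.to_frame().to_csv(sep="\t", index=False))


def write_json(obj, path) -> None:
    atomic_write(path, json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
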