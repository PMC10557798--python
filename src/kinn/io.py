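"""Dataset readers, serialization helpers, splits, and run manifests.

Tables are CSV/TSV (delimiter sniffed from the extension).  The in vitro
schema requires ``guide``, ``target`` and a strictly positive
``cleavage_rate``; the in vivo schema requires ``guide``, ``pam``,
``target_alignment`` and a 0/1 ``label``.  All sequence coordinates in
files and logs are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .encoding import EncodedAlignment, GuideTargetAlignment, encode_invivo, encode_pairing
from .exceptions import DataError
from .kinetics import KineticScheme, RateAssignment, scheme_from_dict, scheme_to_dict

INVITRO_COLUMNS = ("guide", "target", "cleavage_rate")
INVIVO_COLUMNS = ("guide", "pam", "target_alignment", "label")


@dataclass
class AlignmentDataset:
    """Validated records with encodings attached."""

    table: pd.DataFrame
    encodings: list[EncodedAlignment]
    schema: str
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def X(self) -> np.ndarray:
        key = "matrix" if self.schema == "invivo" else "pairing_matrix"
        return np.stack([getattr(e, key) for e in self.encodings])

    @property
    def y(self) -> np.ndarray:
        col = "label" if self.schema == "invivo" else "cleavage_rate"
        return self.table[col].to_numpy(dtype=float)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_alignment_table(path, schema: str, fail_fast: bool = False,
                         L: int = 50) -> AlignmentDataset:
    """Load and validate a gRNA-target table, attaching encodings.

    Malformed rows are collected into ``errors`` (with their row indices)
    and dropped unless ``fail_fast`` raises on the first one.
    """
    if schema not in ("invitro", "invivo"):
        raise DataError(f"unknown schema {schema!r}")
    df = _read_table(path)
    required = INVIVO_COLUMNS if schema == "invivo" else INVITRO_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    keep_rows, encodings, errors = [], [], []
    for idx, row in df.iterrows():
        try:
            if schema == "invitro":
                rate = float(row["cleavage_rate"])
                if not (np.isfinite(rate) and rate > 0):
                    raise DataError(f"cleavage_rate must be positive, got {rate}")
                enc = encode_pairing(str(row["guide"]), str(row["target"]), L=L)
            else:
                label = float(row["label"])
                if label not in (0.0, 1.0):
                    raise DataError(f"label must be 0/1, got {row['label']!r}")
                aln = GuideTargetAlignment(
                    guide=str(row["guide"]),
                    pam=str(row["pam"]),
                    target=str(row["target_alignment"]),
                    guide_alignment=(str(row["guide_alignment"])
                                     if "guide_alignment" in df.columns
                                     and pd.notna(row.get("guide_alignment"))
                                     else None),
                )
                enc = encode_invivo(aln)
        except Exception as exc:  # collect with row index
            msg = f"row {idx}: {exc}"
            if fail_fast:
                raise DataError(msg) from exc
            errors.append(msg)
            continue
        keep_rows.append(idx)
        encodings.append(enc)
    return AlignmentDataset(
        table=df.loc[keep_rows].reset_index(drop=True),
        encodings=encodings,
        schema=schema,
        errors=errors,
    )


def split_by_guide(
    table: pd.DataFrame,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    guide_column: str = "guide",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out a fraction of *guides* (and all their rows), never splitting
    one guide across partitions — avoids sequence leakage."""
    guides = np.asarray(sorted(table[guide_column].unique()))
    if len(guides) < 2:
        raise DataError("need at least 2 distinct guides to split")
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(holdout_fraction * len(guides))))
    if n_hold >= len(guides):
        n_hold = len(guides) - 1
    held = set(rng.choice(guides, size=n_hold, replace=False))
    mask = table[guide_column].isin(held)
    return (table[~mask].reset_index(drop=True),
            table[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_scheme(path, scheme: KineticScheme) -> None:
    with open(path, "w") as fh:
        json.dump(scheme_to_dict(scheme), fh, indent=1)


def load_scheme(path) -> KineticScheme:
    with open(path) as fh:
        return scheme_from_dict(json.load(fh))


def save_rates(path, rates: RateAssignment) -> None:
    with open(path, "w") as fh:
        json.dump(dict(rates.values), fh, indent=1)


def load_rates(path) -> RateAssignment:
    path = str(path)
    if path.endswith(".csv") or path.endswith(".tsv"):
        sep = "\t" if path.endswith(".tsv") else ","
        df = pd.read_csv(path, sep=sep)
        return RateAssignment(dict(zip(df["symbol"], df["value"].astype(float))))
    with open(path) as fh:
        return RateAssignment({k: float(v) for k, v in json.load(fh).items()})


def write_manifest(out_dir, config: dict[str, Any],
                   inputs: dict[str, str] | None = None,
                   outputs: dict[str, str] | None = None) -> Path:
    """Record everything needed to reproduce a run (inputs, config, seed,
    output hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def file_hash(p: str) -> str:
        try:
            return hashlib.sha256(Path(p).read_bytes()).hexdigest()
        except OSError:
            return "unavailable"

    manifest = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "inputs": {k: {"path": v, "sha256": file_hash(v)}
                   for k, v in (inputs or {}).items()},
        "outputs": {k: {"path": v, "sha256": file_hash(v)}
                    for k, v in (outputs or {}).items()},
        "coordinate_convention": "0-based half-open",
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
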