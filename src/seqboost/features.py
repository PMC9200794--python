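"""Feature schema and vector containers shared by both feature families."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureSchema:
    """Canonically ordered, named feature list partitioned into blocks.

    ``blocks`` maps block name -> list of feature names; block order and
    within-block order are fixed so that vectors from different records are
    column-aligned.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_blocks(cls, blocks: list[tuple[str, list[str]]]) -> "FeatureSchema":
        return cls(tuple((name, tuple(names)) for name, names in blocks))

    @property
    def names(self) -> list[str]:
        return [n for _, block in self.blocks for n in block]

    @property
    def block_names(self) -> list[str]:
        return [name for name, _ in self.blocks]

    def block_size(self, name: str) -> int:
        for bname, block in self.blocks:
            if bname == name:
                return len(block)
        raise KeyError(name)

    def block_sizes(self) -> dict[str, int]:
        return {name: len(block) for name, block in self.blocks}

    def __len__(self) -> int:
        return sum(len(block) for _, block in self.blocks)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total": len(self),
            "blocks": [
                {"name": name, "size": len(block), "features": list(block)}
                for name, block in self.blocks
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class FeatureVector:
    """Values aligned to a schema for a single record."""

    record_id: str
    values: np.ndarray
    schema: FeatureSchema = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError(
                f"vector length {self.values.shape} != schema length {len(self.schema)}"
            )

    def __len__(self) -> int:
        return len(self.values)


def matrix_from_vectors(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack per-record vectors into an id-indexed frame."""
    if not vectors:
        raise ValueError("no feature vectors")
    schema = vectors[0].schema
    data = np.vstack([v.values for v in vectors])
    return pd.DataFrame(data, index=[v.record_id for v in vectors], columns=schema.names)


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="id")


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col="id")
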