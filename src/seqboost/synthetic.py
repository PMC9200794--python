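"""Synthetic two-class FASTA generator with batch-structured negatives.

Sequences are drawn i.i.d. from a per-class base composition; gapped
patterns (left word, g wildcard bases, right word) are planted at
Poisson-distributed counts with class-dependent rates by overwriting
background bases, so sequence length is class-independent.  An optional
period-3 bias modulates every third position to give the spectral feature
family a signal.  Default shapes mirror the real datasets the pipeline was
built for: 182 positives with 4 negative batches of 185 ("protein" preset)
and 137 positives with 8 batches of 141 ("lncrna" preset).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import FastaDataset, SequenceRecord

ALPHABET = "ACGT"


@dataclass(frozen=True)
class PlantedPattern:
    left: str
    gap: int
    right: str
    rate_pos: float
    rate_neg: float

    @property
    def span(self) -> int:
        return len(self.left) + self.gap + len(self.right)

    @property
    def feature_name(self) -> str:
        sizes = {1: "mono", 2: "di", 3: "tri"}
        family = (
            f"{sizes[len(self.left)]}{sizes[len(self.right)].capitalize()}KGap"
        )
        return f"{family}_g{self.gap}_{self.left}_{self.right}"


@dataclass
class SyntheticConfig:
    n_pos: int = 100
    n_neg_batches: int = 2
    batch_size: int = 100
    length_range: tuple[int, int] = (300, 500)
    composition_pos: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    composition_neg: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    patterns: tuple[PlantedPattern, ...] = ()
    period3_bias_pos: float = 0.0
    period3_bias_neg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for comp in (self.composition_pos, self.composition_neg):
            if abs(sum(comp) - 1.0) > 1e-12:
                raise ConfigError("composition probabilities must sum to 1")
        max_span = max((p.span for p in self.patterns), default=0)
        if max_span > self.length_range[0]:
            raise ConfigError(
                f"pattern span {max_span} exceeds minimum length {self.length_range[0]}"
            )
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ConfigError("invalid length range")


@dataclass
class GeneratedDataset:
    positives: FastaDataset
    neg_batches: list[FastaDataset]
    informative_features: list[str]
    config: SyntheticConfig

    def all_records(self):
        yield from self.positives.records
        for batch in self.neg_batches:
            yield from batch.records

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.all_records()], dtype=int)


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    composition: np.ndarray,
    patterns: tuple[PlantedPattern, ...],
    positive: bool,
    period3_bias: float,
) -> str:
    bases = rng.choice(4, size=length, p=composition)
    if period3_bias > 0:
        # every third position: with prob `bias` force G (spectral period-3 peak)
        hit = rng.random(length // 3 + 1)[: len(range(0, length, 3))] < period3_bias
        idx = np.arange(0, length, 3)[hit]
        bases[idx] = 2
    seq = np.array([ALPHABET[b] for b in bases])
    for pat in patterns:
        rate = pat.rate_pos if positive else pat.rate_neg
        count = rng.poisson(rate)
        span = pat.span
        for _ in range(count):
            start = int(rng.integers(0, length - span + 1))
            seq[start : start + len(pat.left)] = list(pat.left)
            gap_bases = rng.choice(4, size=pat.gap, p=composition)
            seq[start + len(pat.left) : start + len(pat.left) + pat.gap] = [
                ALPHABET[b] for b in gap_bases
            ]
            seq[start + span - len(pat.right) : start + span] = list(pat.right)
    return "".join(seq)


def generate(cfg: SyntheticConfig) -> GeneratedDataset:
    """Deterministic labeled dataset for the given config and seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    comp_pos = np.asarray(cfg.composition_pos, dtype=float)
    comp_neg = np.asarray(cfg.composition_neg, dtype=float)

    def make(n: int, prefix: str, positive: bool) -> FastaDataset:
        comp = comp_pos if positive else comp_neg
        bias = cfg.period3_bias_pos if positive else cfg.period3_bias_neg
        records = []
        for i in range(n):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            residues = _draw_sequence(
                rng, length, comp, cfg.patterns, positive, bias
            )
            records.append(
                SequenceRecord(
                    id=f"{prefix}_{i:05d}",
                    description="synthetic",
                    residues=residues,
                    label=1 if positive else 0,
                )
            )
        return FastaDataset(records=records, source=f"synthetic:{prefix}")

    positives = make(cfg.n_pos, "pos", True)
    batches = [
        make(cfg.batch_size, f"neg{b}", False) for b in range(cfg.n_neg_batches)
    ]
    informative = [p.feature_name for p in cfg.patterns]
    return GeneratedDataset(
        positives=positives,
        neg_batches=batches,
        informative_features=informative,
        config=cfg,
    )


def permute_labels(ds: GeneratedDataset, seed: int = 0) -> GeneratedDataset:
    """Shuffle which records count as positive/negative; sequences untouched.

    Class and batch sizes are preserved: the pooled records are permuted and
    re-split into a positive set and equally sized negative batches.
    """
    rng = np.random.default_rng(seed)
    records = list(ds.all_records())
    perm = rng.permutation(len(records))
    shuffled = [records[i] for i in perm]
    n_pos = len(ds.positives)
    pos_records = [replace(r, label=1) for r in shuffled[:n_pos]]
    batches = []
    offset = n_pos
    for batch in ds.neg_batches:
        chunk = shuffled[offset : offset + len(batch)]
        batches.append(
            FastaDataset(
                records=[replace(r, label=0) for r in chunk],
                source=batch.source + ":permuted",
            )
        )
        offset += len(batch)
    return GeneratedDataset(
        positives=FastaDataset(records=pos_records, source=ds.positives.source + ":permuted"),
        neg_batches=batches,
        informative_features=[],
        config=ds.config,
    )


PRESETS = {
    "protein": dict(n_pos=182, n_neg_batches=4, batch_size=185),
    "lncrna": dict(n_pos=137, n_neg_batches=8, batch_size=141),
}

DEFAULT_PATTERNS = (
    PlantedPattern("AC", 3, "GT", rate_pos=6.0, rate_neg=0.5),
    PlantedPattern("G", 2, "TA", rate_pos=5.0, rate_neg=0.5),
    PlantedPattern("TTG", 1, "CA", rate_pos=4.0, rate_neg=0.3),
)


def preset_config(
    name: str,
    seed: int = 0,
    length_range: tuple[int, int] = (300, 500),
    patterns: tuple[PlantedPattern, ...] = DEFAULT_PATTERNS,
) -> SyntheticConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SyntheticConfig(
        seed=seed, length_range=length_range, patterns=patterns, **PRESETS[name]
    )


def write_ground_truth(ds: GeneratedDataset, path: str | Path) -> None:
    payload = {
        "informative_features": ds.informative_features,
        "labels": {r.id: r.label for r in ds.all_records()},
        "config": asdict(ds.config),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
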