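"""File formats: pattern-count TSV, layout YAML, sterility TSV.

All tables are UTF-8 tab-separated text with ``#`` comment lines and ``.``
decimal separators.  Genetic lengths are Morgans internally; layout files
state them in centiMorgans (the unit geneticists publish maps in).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .inference import PatternDataset
from .karyotype import ChromosomeLayout, Placement
from .sterility import SterilityRecord

__all__ = [
    "read_pattern_dataset",
    "write_pattern_dataset",
    "read_layout",
    "write_layout",
    "read_sterility",
    "write_sterility",
]

logger = logging.getLogger("perinv")


def read_pattern_dataset(path) -> PatternDataset:
    """Read a pattern-count TSV.

    The header row holds the n+1 marker names; each following row is a
    binary pattern string over the n intervals (interval 0 first) and a
    count.  Missing patterns are imputed as zero counts with a warning.
    """
    path = Path(path)
    lines = [
        line.rstrip("\n")
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty pattern file")
    marker_names = lines[0].split("\t")
    if len(marker_names) < 2:
        raise ValueError(f"{path}: header must list at least two marker names")
    n = len(marker_names) - 1
    counts: dict[str, int] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: malformed row {line!r}")
        pattern, count_s = fields
        if len(pattern) != n or set(pattern) - {"0", "1"}:
            raise ValueError(f"{path}: malformed pattern string {pattern!r}")
        count = int(count_s)
        if count < 0:
            raise ValueError(f"{path}: negative count in row {line!r}")
        counts[pattern] = counts.get(pattern, 0) + count
    if len(counts) < 2**n:
        logger.warning(
            "%s: %d of %d patterns absent; imputing zero counts",
            path, 2**n - len(counts), 2**n,
        )
    return PatternDataset.from_counts_dict(marker_names, counts)


def write_pattern_dataset(dataset: PatternDataset, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(dataset.marker_names) + "\n")
        for code in range(dataset.counts.size):
            fh.write(f"{dataset.pattern_string(code)}\t{int(dataset.counts[code])}\n")


def _placement_from(cfg, key: str) -> Placement | None:
    if key not in cfg or cfg[key] is None:
        return None
    entry = cfg[key]
    return Placement(int(entry["interval"]), float(entry["fraction"]))


def read_layout(path) -> ChromosomeLayout:
    """Read a chromosome-layout YAML file.

    Keys: ``marker_names`` (list), ``karyotype`` (hetero|homo),
    ``left_breakpoint``/``centromere``/``right_breakpoint`` (mappings with
    ``interval`` and ``fraction``), optional ``lengths_cM`` and
    ``homokaryotype_lengths_cM`` per interval.
    """
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(cfg, dict) or "marker_names" not in cfg:
        raise ValueError(f"{path}: layout file must define marker_names")

    def lengths(key):
        if key not in cfg or cfg[key] is None:
            return None
        return np.asarray(cfg[key], dtype=float) / 100.0

    return ChromosomeLayout(
        marker_names=tuple(cfg["marker_names"]),
        karyotype=cfg.get("karyotype", "hetero"),
        left_bp=_placement_from(cfg, "left_breakpoint"),
        centromere=_placement_from(cfg, "centromere"),
        right_bp=_placement_from(cfg, "right_breakpoint"),
        l_prime=lengths("lengths_cM"),
        l_homo=lengths("homokaryotype_lengths_cM"),
    )


def write_layout(layout: ChromosomeLayout, path) -> None:
    cfg: dict = {
        "marker_names": list(layout.marker_names),
        "karyotype": layout.karyotype,
    }
    for key, p in (
        ("left_breakpoint", layout.left_bp),
        ("centromere", layout.centromere),
        ("right_breakpoint", layout.right_bp),
    ):
        if p is not None:
            cfg[key] = {"interval": p.interval, "fraction": p.fraction}
    if layout.l_prime is not None:
        cfg["lengths_cM"] = [float(x) for x in 100.0 * layout.l_prime]
    if layout.l_homo is not None:
        cfg["homokaryotype_lengths_cM"] = [float(x) for x in 100.0 * layout.l_homo]
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")


def read_sterility(path) -> list[SterilityRecord]:
    """Read a sterility TSV: inversion_id, I_morgans, rho, observed_sterility."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"inversion_id", "I_morgans", "rho", "observed_sterility"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SterilityRecord(str(r.inversion_id), float(r.I_morgans), float(r.rho),
                        float(r.observed_sterility))
        for r in frame.itertuples(index=False)
    ]


def write_sterility(records: Sequence[SterilityRecord], path) -> None:
    frame = pd.DataFrame(
        [(r.inversion_id, r.I, r.rho, r.observed) for r in records],
        columns=["inversion_id", "I_morgans", "rho", "observed_sterility"],
    )
    frame.to_csv(path, sep="\t", index=False)
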