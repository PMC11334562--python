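"""Loaders for the shipped residue property tables.

Tables live as plain TSV under ``dpicdf/data`` so users can substitute
their own group assignments or scales without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .sequence_io import CANONICAL_RESIDUES


def _data_path(name: str):
    return resources.files("dpicdf.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t")


def _check_partition(mapping: dict[str, int], context: str) -> None:
    missing = set(CANONICAL_RESIDUES) - set(mapping)
    if missing:
        raise ValueError(f"{context}: residues missing from table: {sorted(missing)}")


@lru_cache(maxsize=None)
def ctd_groupings() -> dict[str, dict[str, int]]:
    """property -> residue -> group label (1, 2 or 3)."""
    df = _read_tsv("ctd_groups.tsv")
    out: dict[str, dict[str, int]] = {}
    for prop, sub in df.groupby("property", sort=False):
        mapping = dict(zip(sub["residue"], sub["group"].astype(int)))
        _check_partition(mapping, f"CTD property {prop!r}")
        out[str(prop)] = mapping
    return out


@lru_cache(maxsize=None)
def cpsr_groupings() -> dict[str, dict[str, int]]:
    """scheme (exchange / electron / r_group) -> residue -> class label."""
    df = _read_tsv("cpsr_groups.tsv")
    out: dict[str, dict[str, int]] = {}
    for scheme, sub in df.groupby("scheme", sort=False):
        mapping = dict(zip(sub["residue"], sub["class"].astype(int)))
        _check_partition(mapping, f"CPSR scheme {scheme!r}")
        out[str(scheme)] = mapping
    return out


@lru_cache(maxsize=None)
def cpsr_scales() -> dict[str, dict[str, float]]:
    """scale (rigidity / flexibility / irreplaceability) -> residue -> value."""
    df = _read_tsv("cpsr_scales.tsv")
    out: dict[str, dict[str, float]] = {}
    for scale, sub in df.groupby("scale", sort=False):
        mapping = dict(zip(sub["residue"], sub["value"].astype(float)))
        _check_partition(mapping, f"CPSR scale {scale!r}")
        out[str(scale)] = mapping
    return out
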