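"""Trait tables and polymorphic-state coding.

Presence/absence of the baculum (penis bone) and baubellum (clitoris bone)
is scored per species as ``present``, ``absent`` or ``polymorphic`` (some but
not all adult females carry the bone).  Because a polymorphic score admits
several biological interpretations, four coding strategies are supported for
downstream character mapping:

``polymorphic``
    keep it as a third character state;
``present``
    recode as present (a normally developing but incompletely penetrant or
    under-observed trait);
``absent``
    recode as absent (a trait that normally does not develop);
``random``
    draw present/absent independently and fairly per polymorphic species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["STATES", "STRATEGIES", "TraitRecord", "CodedDataset",
           "read_trait_table", "read_alias_map", "recode_states"]

log = logging.getLogger(__name__)

STATES = ("present", "absent", "polymorphic")
STRATEGIES = ("polymorphic", "present", "absent", "random")
BONES = ("baculum", "baubellum")

_STATE_ALIASES = {"present": "present", "absent": "absent",
                  "polymorphic": "polymorphic", "1": "present", "0": "absent"}


@dataclass(frozen=True)
class TraitRecord:
    """Scored bone states for one species."""
    species: str
    baculum: str
    baubellum: str

    def __post_init__(self):
        if not self.species:
            raise ValueError("species name must be nonempty")
        for bone in BONES:
            if getattr(self, bone) not in STATES:
                raise ValueError(f"invalid {bone} state {getattr(self, bone)!r} "
                                 f"for {self.species!r}; expected one of {STATES}")

    def state(self, bone: str) -> str:
        if bone not in BONES:
            raise ValueError(f"bone must be one of {BONES}")
        return getattr(self, bone)


@dataclass(frozen=True)
class CodedDataset:
    """Per-species coded states for one bone under one coding strategy."""
    strategy: str
    bone: str
    states: tuple[str, ...]
    codes: Mapping[str, str]
    seed: int | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        expected = 3 if self.strategy == "polymorphic" else 2
        if len(self.states) != expected:
            raise ValueError(f"strategy {self.strategy!r} implies {expected} states, "
                             f"got {self.states}")
        bad = {sp: st for sp, st in self.codes.items() if st not in self.states}
        if bad:
            raise ValueError(f"coded states outside the state space: {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.codes)

    def state_index(self, species: str) -> int:
        return self.states.index(self.codes[species])


def _normalize_state(raw: object, row_repr: str) -> str:
    token = str(raw).strip().lower()
    if token not in _STATE_ALIASES:
        raise ValueError(f"unknown trait state {raw!r} in row {row_repr}")
    return _STATE_ALIASES[token]


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping of taxon-name aliases (from, to)."""
    df = pd.read_csv(path, header=None, comment="#",
                     names=["from_name", "to_name"], skipinitialspace=True)
    return {str(a).strip(): str(b).strip()
            for a, b in zip(df["from_name"], df["to_name"])}


def read_trait_table(path: str | Path,
                     alias_map: Mapping[str, str] | None = None) -> list[TraitRecord]:
    """Read a CSV/TSV trait table with columns species, baculum, baubellum.

    Header matching is case-insensitive; the separator is sniffed.  State
    strings are normalized (case-insensitive; 1/0 accepted for
    present/absent).  Taxon aliases, if given, are applied at read time.
    """
    df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    cols = {c.strip().lower(): c for c in df.columns}
    needed = ["species", "baculum", "baubellum"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"trait table is missing columns {missing}; "
                         f"found {list(df.columns)}")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        row_repr = ",".join(str(row[cols[c]]) for c in needed)
        species = str(row[cols["species"]]).strip()
        if alias_map and species in alias_map:
            species = alias_map[species]
        if species in seen:
            raise ValueError(f"duplicate species {species!r} in trait table")
        seen.add(species)
        records.append(TraitRecord(
            species=species,
            baculum=_normalize_state(row[cols["baculum"]], row_repr),
            baubellum=_normalize_state(row[cols["baubellum"]], row_repr),
        ))
    return records


def recode_states(records: Sequence[TraitRecord], bone: str, strategy: str,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> CodedDataset:
    """Apply one polymorphic-coding strategy to one bone.

    Non-polymorphic species always keep their scored state.  Polymorphic
    species map to the third state (``polymorphic``), to ``present``, to
    ``absent``, or to an independent fair draw from {present, absent}
    (``random``; requires a seed or generator).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if bone not in BONES:
        raise ValueError(f"bone must be one of {BONES}, got {bone!r}")
    if strategy == "random" and seed is None and rng is None:
        raise ValueError("strategy 'random' requires a seed (or an explicit rng)")
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)

    states = STATES if strategy == "polymorphic" else ("present", "absent")
    codes: dict[str, str] = {}
    for rec in records:
        st = rec.state(bone)
        if st == "polymorphic":
            if strategy == "polymorphic":
                codes[rec.species] = "polymorphic"
            elif strategy == "random":
                codes[rec.species] = "present" if rng.random() < 0.5 else "absent"
            else:
                codes[rec.species] = strategy
        else:
            codes[rec.species] = st
    return CodedDataset(strategy=strategy, bone=bone, states=tuple(states),
                        codes=codes, seed=seed)


def intersect_with_tree(records: Sequence[TraitRecord],
                        tip_labels: Iterable[str]) -> list[TraitRecord]:
    """Keep the records whose species are on the tree, warning about drops."""
    tips = set(tip_labels)
    kept = [r for r in records if r.species in tips]
    dropped = [r.species for r in records if r.species not in tips]
    if dropped:
        log.warning("dropping %d species absent from the tree: %s",
                    len(dropped), ", ".join(sorted(dropped)[:10]) +
                    ("..." if len(dropped) > 10 else ""))
    return kept
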