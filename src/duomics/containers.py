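"""Core data containers: omics matrices and gene-set collections.

An :class:`OmicsMatrix` is a thin, validated wrapper around a samples x
features :class:`pandas.DataFrame`. The same container holds log2-scale
expression values (``kind="expression"``), compositional relative abundances
(``kind="abundance"``, rows on the unit simplex) and centered log-ratio
transformed compositions (``kind="clr"``).

A :class:`GeneSetCollection` holds named gene sets with descriptions and
round-trips through the standard GMT text format
(``name<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "GeneSetCollection"]

_KINDS = ("expression", "abundance", "clr")

# Filtering removes species from a composition without renormalising, so a
# filtered abundance matrix has row sums <= 1; full compositions sum to 1.
_SIMPLEX_TOL = 1e-8


@dataclass
class OmicsMatrix:
    """Samples x features real matrix with identifiers and a kind tag.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
    kind
        One of ``"expression"``, ``"abundance"``, ``"clr"``.
    """

    values: pd.DataFrame
    kind: str = "expression"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature identifiers")
        if self.kind == "abundance":
            vals = self.values.to_numpy()
            if vals.size and (vals < -_SIMPLEX_TOL).any():
                raise ValueError("abundance entries must be non-negative")
            sums = vals.sum(axis=1)
            if vals.size and (sums > 1.0 + _SIMPLEX_TOL).any():
                raise ValueError("abundance rows must sum to at most 1")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_full_composition(self) -> bool:
        """True if every row sums to 1 within tolerance (unfiltered composition)."""
        sums = self.values.to_numpy().sum(axis=1)
        return bool(np.all(np.abs(sums - 1.0) <= _SIMPLEX_TOL))

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``feature_ids`` (sample order preserved)."""
        return OmicsMatrix(self.values.loc[:, list(feature_ids)].copy(), kind=self.kind)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(sample_ids)].copy(), kind=self.kind)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        """Write as TSV: first column sample id, header row of feature ids.

        ``comment`` lines (e.g. a run manifest tag) are written first,
        prefixed with ``#``.
        """
        path = Path(path)
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "expression") -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, kind=kind)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with a source tag.

    ``sets`` maps set name -> (description, tuple of member gene ids).
    Member lists are non-empty and duplicate-free within a set.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, genes) in self.sets.items():
            genes = tuple(genes)
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            clean[name] = (desc, genes)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        genes = tuple(genes)
        if not genes:
            raise ValueError("cannot add an empty gene set")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in set")
        self.sets[name] = (description, genes)

    def as_dict(self) -> dict[str, list[str]]:
        """Plain name -> gene list mapping (drops descriptions)."""
        return {name: list(genes) for name, (_, genes) in self.sets.items()}

    # -- GMT I/O -----------------------------------------------------------
    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (desc, genes) in self.sets.items():
                fh.write("\t".join([name, desc, *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path, source: str = "") -> "GeneSetCollection":
        sets: dict[str, tuple[str, tuple[str, ...]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                name, desc, genes = parts[0], parts[1], parts[2:]
                sets[name] = (desc, tuple(g for g in genes if g))
        return cls(sets=sets, source=source)


def as_mapping(groups, sample_ids: Sequence[str]) -> dict[str, str]:
    """Normalise a sample->group specification to a plain dict covering samples.

    Accepts a dict, a pandas Series indexed by sample id, or a sequence
    aligned with ``sample_ids``.
    """
    if isinstance(groups, pd.Series):
        mapping = groups.to_dict()
    elif isinstance(groups, Mapping):
        mapping = dict(groups)
    else:
        seq = list(groups)
        if len(seq) != len(sample_ids):
            raise ValueError("group sequence length does not match samples")
        mapping = dict(zip(sample_ids, seq))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    return mapping
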