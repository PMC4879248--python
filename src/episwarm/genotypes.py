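"""Labeled genotype matrices and genotype-pattern matching.

A sample's genotype at a SNP is coded on the three-letter alphabet
``{1, 2, 3}``: 1 = major homozygote, 2 = minor homozygote, 3 = heterozygote.
A *genotype pattern* is a conjunction of (SNP, genotype) requirements; a
sample *carries* the pattern iff every requirement holds exactly.  Carrier
counting against case/control labels yields the 2x2 table that every
association statistic in this package is built on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CODES = (1, 2, 3)
CASE = "case"
CONTROL = "control"

_LABEL_ALIASES = {"case": CASE, "1": CASE, "control": CONTROL, "0": CONTROL}


class GenotypeError(ValueError):
    """Raised for malformed genotype data or patterns."""


@dataclass(frozen=True, order=True)
class SNPPattern:
    """A genotype-pattern interaction: a set of (SNP index, genotype code) pairs.

    Entries are stored sorted by SNP index (canonical form) so that patterns
    compare and hash by content.  SNP indices are 0-based internally; reports
    render them 1-based.
    """

    entries: tuple[tuple[int, int], ...]

    def __init__(self, entries):
        entries = tuple(sorted((int(i), int(g)) for i, g in entries))
        indices = [i for i, _ in entries]
        if len(set(indices)) != len(indices):
            raise GenotypeError(f"duplicate SNP index in pattern: {entries}")
        for i, g in entries:
            if i < 0:
                raise GenotypeError(f"negative SNP index {i}")
            if g not in GENOTYPE_CODES:
                raise GenotypeError(f"genotype code {g} not in {GENOTYPE_CODES}")
        object.__setattr__(self, "entries", entries)

    @property
    def order(self) -> int:
        """Number of SNPs in the pattern (its interaction order k)."""
        return len(self.entries)

    @property
    def snp_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    def matches(self, sample) -> bool:
        """True iff ``sample`` has exactly the required genotype at every entry.

        The empty pattern matches vacuously.
        """
        sample = np.asarray(sample)
        for i, g in self.entries:
            if i >= sample.shape[-1]:
                raise GenotypeError(
                    f"pattern index {i} out of range for sample of length {sample.shape[-1]}"
                )
            if sample[i] != g:
                return False
        return True

    def to_string(self, snp_ids=None) -> str:
        """Render as ``rsX(g)-rsY(g)``; falls back to 1-based ``SNP<k>`` names."""
        parts = []
        for i, g in self.entries:
            name = snp_ids[i] if snp_ids is not None else f"SNP{i + 1}"
            parts.append(f"{name}({g})")
        return "-".join(parts)

    @classmethod
    def from_string(cls, text: str, snp_ids) -> "SNPPattern":
        index = {s: i for i, s in enumerate(snp_ids)}
        entries = []
        for part in text.split("-"):
            m = re.fullmatch(r"(.+)\((\d)\)", part.strip())
            if not m:
                raise GenotypeError(f"cannot parse pattern component {part!r}")
            name, g = m.group(1), int(m.group(2))
            if name not in index:
                raise GenotypeError(f"unknown SNP id {name!r} in pattern")
            entries.append((index[name], g))
        return cls(entries)

    def to_json_obj(self, snp_ids) -> list[dict]:
        return [{"snp": snp_ids[i], "genotype": g} for i, g in self.entries]

    @classmethod
    def from_json_obj(cls, obj, snp_ids) -> "SNPPattern":
        index = {s: i for i, s in enumerate(snp_ids)}
        return cls([(index[e["snp"]], int(e["genotype"])) for e in obj])


@dataclass(frozen=True)
class CarrierCounts:
    """2x2 carrier table of a pattern against case/control labels.

    a: case carriers, b: case non-carriers, c: control carriers,
    d: control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise GenotypeError(f"carrier counts must be non-negative integers, got {self}")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class LabeledGenotypes:
    """An m-samples x n-SNPs genotype matrix with case/control labels.

    ``genotypes`` holds codes in {1,2,3}; ``labels`` holds "case"/"control".
    Validation happens on construction: any other code, a duplicate SNP id, or
    a missing value is rejected (missing genotypes are unsupported).
    """

    genotypes: np.ndarray
    labels: np.ndarray
    snp_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeError("genotype matrix must be 2-dimensional")
        m, n = self.genotypes.shape
        bad = ~np.isin(self.genotypes, GENOTYPE_CODES)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.genotypes[r, c]} at sample row {r}, SNP column {c}"
            )
        labels = np.asarray(
            [_LABEL_ALIASES.get(str(x).strip().lower()) for x in np.asarray(self.labels).ravel()]
        )
        if any(x is None for x in labels):
            raise GenotypeError(f"labels must be case/control or 1/0, got {set(map(str, self.labels))}")
        if labels.shape[0] != m:
            raise GenotypeError("label vector length does not match sample count")
        self.labels = labels.astype("U7")
        if self.snp_ids is None:
            self.snp_ids = [f"SNP{i + 1}" for i in range(n)]
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(m)]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.snp_ids) != n:
            raise GenotypeError("snp_ids length does not match SNP count")
        if len(set(self.snp_ids)) != n:
            raise GenotypeError("duplicate snp_id")
        if len(self.sample_ids) != m:
            raise GenotypeError("sample_ids length does not match sample count")

    @property
    def m(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return self.labels == CASE

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return self.m - self.n_case

    def subset(self, row_indices) -> "LabeledGenotypes":
        idx = np.asarray(row_indices)
        return LabeledGenotypes(
            self.genotypes[idx],
            self.labels[idx],
            snp_ids=self.snp_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def carrier_mask(pattern: SNPPattern, genotypes: np.ndarray) -> np.ndarray:
    """Boolean per-sample carrier indicator, vectorized over the matrix rows."""
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[1]
    mask = np.ones(genotypes.shape[0], dtype=bool)
    for i, g in pattern.entries:
        if i >= n:
            raise GenotypeError(f"pattern index {i} out of range for {n} SNPs")
        mask &= genotypes[:, i] == g
    return mask


def matches(pattern: SNPPattern, sample) -> bool:
    return pattern.matches(sample)


def carrier_counts(pattern: SNPPattern, data: LabeledGenotypes) -> CarrierCounts:
    """Count pattern carriers in the case and control groups.

    Requires both classes present; association statistics are meaningless
    otherwise.
    """
    if data.n_case == 0 or data.n_control == 0:
        raise GenotypeError("carrier_counts requires both cases and controls")
    carriers = carrier_mask(pattern, data.genotypes)
    is_case = data.is_case
    a = int(np.count_nonzero(carriers & is_case))
    c = int(np.count_nonzero(carriers & ~is_case))
    return CarrierCounts(a=a, b=data.n_case - a, c=c, d=data.n_control - c)


def read_genotypes(path, delimiter=None) -> LabeledGenotypes:
    """Load a delimited genotype table: ``sample_id, label, <snp_id>...``.

    Comma and tab are auto-detected unless ``delimiter`` is given.  Labels may
    be case/control or 1/0.  Any cell outside {1,2,3} aborts the load with the
    offending sample and SNP named.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if df.shape[1] < 3:
        raise GenotypeError("genotype file needs sample_id, label and at least one SNP column")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].astype(str).tolist()
    snp_ids = [str(c) for c in df.columns[2:]]
    raw = df.iloc[:, 2:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~numeric.isin(GENOTYPE_CODES)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise GenotypeError(
            f"invalid genotype code {raw.iat[r, c]!r} for sample {sample_ids[r]!r}, SNP {snp_ids[c]!r}"
        )
    return LabeledGenotypes(
        numeric.to_numpy(dtype=np.int8), labels, snp_ids=snp_ids, sample_ids=sample_ids
    )


def write_genotypes(data: LabeledGenotypes, path, delimiter=",") -> None:
    """Write a LabeledGenotypes back to the delimited format read_genotypes reads."""
    df = pd.DataFrame(data.genotypes, columns=data.snp_ids)
    df.insert(0, "label", data.labels)
    df.insert(0, "sample_id", data.sample_ids)
    df.to_csv(path, sep=delimiter, index=False)


def patterns_to_json(patterns_with_or, snp_ids) -> str:
    """Serialize [(SNPPattern, odds_ratio), ...] to the interop JSON form."""
    return json.dumps(
        [
            {"pattern": p.to_json_obj(snp_ids), "odds_ratio": float(o)}
            for p, o in patterns_with_or
        ],
        indent=1,
    )


def patterns_from_json(text: str, snp_ids):
    return [
        (SNPPattern.from_json_obj(e["pattern"], snp_ids), float(e["odds_ratio"]))
        for e in json.loads(text)
    ]
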