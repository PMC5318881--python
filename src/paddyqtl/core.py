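"""Shared containers: genetic maps and genotype matrices.

Genotype calls are held as small-integer codes for fast vectorised work:
``0 = A`` (IR64-like parent), ``1 = H`` (heterozygous), ``2 = B``
(Aswina-like parent), ``-1 = missing``.  The additive dosage convention is
A = -1, H = 0, B = +1, so an "additive effect" is the effect per Aswina
allele and the gap between homozygote classes is twice the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CODE_A = 0
CODE_H = 1
CODE_B = 2
CODE_MISSING = -1

_CALL_TO_CODE = {"A": CODE_A, "H": CODE_H, "B": CODE_B}
_CODE_TO_CALL = {CODE_A: "A", CODE_H: "H", CODE_B: "B", CODE_MISSING: "NA"}


@dataclass(frozen=True)
class Chromosome:
    """Ordered markers on one linkage group, positions in Kosambi cM."""

    name: str
    markers: tuple[str, ...]
    positions: np.ndarray  # cM, strictly increasing, >= 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.markers) != len(pos):
            raise ValueError(f"chromosome {self.name}: markers/positions length mismatch")
        if len(pos) and pos[0] < 0:
            raise ValueError(f"chromosome {self.name}: negative position")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {self.name}: positions not strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0


@dataclass(frozen=True)
class GeneticMap:
    """A set of chromosomes with ordered marker positions (cM)."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m in seen:
                    raise ValueError(f"duplicate marker id {m!r}")
                seen.add(m)

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    @property
    def marker_ids(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    def marker_position(self, marker_id: str) -> tuple[str, float]:
        """Return (chromosome name, cM position) of a marker."""
        for c in self.chromosomes:
            try:
                i = c.markers.index(marker_id)
            except ValueError:
                continue
            return c.name, float(c.positions[i])
        raise KeyError(f"marker {marker_id!r} not on map")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, c.name, p)
            for c in self.chromosomes
            for m, p in zip(c.markers, c.positions)
        ]
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        chroms = []
        for name, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos_cM", kind="stable")
            chroms.append(
                Chromosome(str(name), tuple(grp["marker"].astype(str)), grp["pos_cM"].to_numpy(float))
            )
        return cls(tuple(chroms))

    def subset(self, keep_markers) -> "GeneticMap":
        keep = set(keep_markers)
        chroms = []
        for c in self.chromosomes:
            idx = [i for i, m in enumerate(c.markers) if m in keep]
            if idx:
                chroms.append(
                    Chromosome(c.name, tuple(c.markers[i] for i in idx), c.positions[idx])
                )
        return GeneticMap(tuple(chroms))


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix with integer coding (see module docstring)."""

    codes: np.ndarray  # int8, (n_lines, n_markers)
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def dosage(self) -> np.ndarray:
        """Additive dosage (A=-1, H=0, B=+1); missing -> NaN."""
        d = self.codes.astype(float) - 1.0
        d[self.codes == CODE_MISSING] = np.nan
        return d

    # --- per-marker / per-line statistics -------------------------------
    def marker_missing_fraction(self) -> np.ndarray:
        return (self.codes == CODE_MISSING).mean(axis=0)

    def marker_allele_A_fraction(self) -> np.ndarray:
        """Fraction of A calls among non-missing, non-H calls per marker."""
        a = (self.codes == CODE_A).sum(axis=0).astype(float)
        b = (self.codes == CODE_B).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(a + b > 0, a / (a + b), np.nan)

    def marker_het_fraction(self) -> np.ndarray:
        called = (self.codes != CODE_MISSING).sum(axis=0).astype(float)
        h = (self.codes == CODE_H).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, h / called, np.nan)

    def line_het_fraction(self) -> np.ndarray:
        called = (self.codes != CODE_MISSING).sum(axis=1).astype(float)
        h = (self.codes == CODE_H).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, h / called, np.nan)

    def line_missing_fraction(self) -> np.ndarray:
        return (self.codes == CODE_MISSING).mean(axis=1)

    # --- subsetting -----------------------------------------------------
    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            self.codes[np.ix_(li, mi)],
            [self.line_ids[i] for i in li],
            [self.marker_ids[j] for j in mi],
        )

    def subset_marker_ids(self, marker_ids) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return self.subset(markers=idx)

    # --- conversion -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        calls = np.vectorize(_CODE_TO_CALL.get)(self.codes)
        df = pd.DataFrame(calls, index=self.line_ids, columns=self.marker_ids)
        df.index.name = "line"
        return df.replace("NA", pd.NA)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        codes = np.full(df.shape, CODE_MISSING, dtype=np.int8)
        vals = df.where(df.notna(), "NA").to_numpy(dtype=str)
        for call, code in _CALL_TO_CODE.items():
            codes[vals == call] = code
        return cls(codes, [str(i) for i in df.index], [str(c) for c in df.columns])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.copy(), list(self.line_ids), list(self.marker_ids))


def rng_for(seed: int, *stream: object) -> np.random.Generator:
    """Named substream generator: one master seed, independent stages.

    The stream labels are hashed into the seed sequence so each pipeline
    stage draws from its own reproducible stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for s in stream:
        h = 2166136261
        for ch in str(s).encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        entropy.append(h)
    return np.random.default_rng(np.random.SeedSequence(entropy))
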