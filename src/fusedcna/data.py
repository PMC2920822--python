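"""Core domain types and text-format I/O for aCGH cohort analysis.

An aCGH cohort is a samples x probes matrix of log2 copy-number ratios
together with an ordered probe annotation (chromosome, base-pair
position, chromosomal arm).  Probe order defines the adjacency used by
the fusion constraints, so both containers validate and enforce a
canonical genomic sort on construction.

Formats
-------
* matrix TSV: first column the sample id, remaining columns one probe each;
* annotation TSV: columns ``probe_id``, ``chromosome``, ``position``
  (1-based), ``arm`` (``p`` or ``q``);
* CNA calls: BED (0-based half-open) or SEG (1-based inclusive).

Lines starting with ``#`` are treated as comments (provenance headers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "CNACall",
    "FormatError",
    "ProbeMap",
    "ProfileMatrix",
    "read_profiles",
    "write_cna_calls",
    "write_profiles",
]


class FormatError(ValueError):
    """Malformed or inconsistent input files (e.g. mismatched probe sets)."""


class AnnotationError(ValueError):
    """Invalid probe annotation (duplicate positions, interleaved arms...)."""


def chromosome_sort_key(chromosome: str) -> tuple:
    """Natural ordering for chromosome labels: 1..22 numerically, then others.

    Accepts labels with or without a ``chr`` prefix.
    """
    label = str(chromosome)
    core = re.sub(r"^chr", "", label, flags=re.IGNORECASE)
    if core.isdigit():
        return (0, int(core), "")
    return (1, 0, core)


@dataclass(frozen=True)
class ProbeMap:
    """Ordered probe annotations defining adjacency for fusion constraints.

    Probes are sorted by (chromosome, position); positions are strictly
    increasing within a chromosome and all ``p``-arm probes precede the
    ``q``-arm ones.
    """

    probe_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    arm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=object))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=np.int64))
        object.__setattr__(self, "arm", np.asarray(self.arm, dtype=object))
        n = len(self.probe_ids)
        if not (len(self.chromosome) == len(self.position) == len(self.arm) == n):
            raise AnnotationError("probe annotation columns have unequal lengths")
        bad_arms = set(self.arm) - {"p", "q"}
        if bad_arms:
            raise AnnotationError(f"arm labels must be 'p' or 'q', got {sorted(bad_arms)}")
        for chrom, start, stop in self._chromosome_runs():
            pos = self.position[start:stop]
            if np.any(np.diff(pos) <= 0):
                raise AnnotationError(
                    f"positions on chromosome {chrom} are not strictly increasing"
                )
            arms = self.arm[start:stop]
            seen_q = False
            for a in arms:
                if a == "q":
                    seen_q = True
                elif seen_q:
                    raise AnnotationError(
                        f"chromosome {chrom} has a p-arm probe after a q-arm probe"
                    )

    def _chromosome_runs(self) -> list[tuple[str, int, int]]:
        runs = []
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chromosome[i] != self.chromosome[start]:
                runs.append((self.chromosome[start], start, i))
                start = i
        return runs

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels, in probe order."""
        return [chrom for chrom, _, _ in self._chromosome_runs()]

    def arm_segments(self) -> list[tuple[str, str, int, int]]:
        """Maximal (chromosome, arm, start, stop) index runs, stop exclusive."""
        segments = []
        for chrom, cstart, cstop in self._chromosome_runs():
            start = cstart
            for i in range(cstart + 1, cstop + 1):
                if i == cstop or self.arm[i] != self.arm[start]:
                    segments.append((chrom, self.arm[start], start, i))
                    start = i
        return segments

    def chromosome_indices(self, chromosome: str) -> np.ndarray:
        idx = np.flatnonzero(self.chromosome == chromosome)
        if idx.size == 0:
            raise KeyError(f"no probes on chromosome {chromosome!r}")
        return idx

    def subset(self, indices: np.ndarray) -> "ProbeMap":
        return ProbeMap(
            self.probe_ids[indices],
            self.chromosome[indices],
            self.position[indices],
            self.arm[indices],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProbeMap":
        required = {"probe_id", "chromosome", "position", "arm"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"annotation is missing columns {sorted(missing)}")
        frame = frame.copy()
        frame["chromosome"] = frame["chromosome"].astype(str)
        frame["arm"] = frame["arm"].astype(str)
        key = frame["chromosome"].map(chromosome_sort_key)
        order = sorted(range(len(frame)), key=lambda i: (key.iloc[i], frame["position"].iloc[i]))
        frame = frame.iloc[order]
        dup = frame.duplicated(subset=["chromosome", "position"])
        if dup.any():
            where = frame.loc[dup, ["chromosome", "position"]].iloc[0]
            raise AnnotationError(
                "duplicate genomic position "
                f"{where['chromosome']}:{where['position']} in annotation"
            )
        return cls(
            frame["probe_id"].to_numpy(dtype=object),
            frame["chromosome"].to_numpy(dtype=object),
            frame["position"].to_numpy(),
            frame["arm"].to_numpy(dtype=object),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chromosome": self.chromosome,
                "position": self.position,
                "arm": self.arm,
            }
        )


@dataclass(frozen=True)
class ProfileMatrix:
    """Samples x probes matrix of log2 ratios tied to a :class:`ProbeMap`."""

    sample_ids: list[str]
    values: np.ndarray
    probe_map: ProbeMap

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise FormatError("profile values must be a 2-D matrix")
        if self.values.shape[0] != len(self.sample_ids):
            raise FormatError("row count does not match number of sample ids")
        if self.values.shape[1] != len(self.probe_map):
            raise FormatError("column count does not match probe annotation length")
        if np.isnan(self.values).any():
            raise FormatError("profile matrix contains missing values after policy")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def restrict_chromosome(self, chromosome: str) -> "ProfileMatrix":
        idx = self.probe_map.chromosome_indices(chromosome)
        return ProfileMatrix(
            list(self.sample_ids), self.values[:, idx], self.probe_map.subset(idx)
        )

    def subset_samples(self, selector) -> "ProfileMatrix":
        """Restrict to a sample subset given as a boolean mask or index array."""
        selector = np.asarray(selector)
        if selector.dtype == bool:
            selector = np.flatnonzero(selector)
        ids = [self.sample_ids[i] for i in selector]
        return ProfileMatrix(ids, self.values[selector], self.probe_map)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.probe_map.probe_ids,
        )


@dataclass(frozen=True)
class CNACall:
    """A gain or loss attributed to a sample cluster.

    Probe indices are inclusive and refer to the probe map the call was
    made against; base-pair coordinates are 1-based inclusive.
    """

    chromosome: str
    start_probe: int
    end_probe: int
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    mean_amplitude: float
    node_id: str = ""
    n_samples: int = 0

    def __post_init__(self):
        if self.start_probe > self.end_probe:
            raise ValueError("start_probe must not exceed end_probe")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")
        sign = 1.0 if self.direction == "gain" else -1.0
        if sign * self.mean_amplitude <= 0:
            raise ValueError("sign of mean_amplitude must match direction")

    @property
    def n_probes(self) -> int:
        return self.end_probe - self.start_probe + 1


def _apply_missing_policy(
    frame: pd.DataFrame, policy: str, max_missing_fraction: float = 0.2
) -> pd.DataFrame:
    """Resolve missing entries.

    ``impute`` (default): drop probes missing in more than
    ``max_missing_fraction`` of samples, median-impute the rest.  ``drop``:
    drop every probe with any missing entry.  ``error``: refuse.
    """
    if policy == "error":
        if frame.isna().any().any():
            raise FormatError("matrix contains missing values and policy is 'error'")
        return frame
    if policy == "drop":
        return frame.loc[:, frame.notna().all(axis=0)]
    if policy == "impute":
        frac = frame.isna().mean(axis=0)
        kept = frame.loc[:, frac <= max_missing_fraction]
        return kept.fillna(kept.median(axis=0))
    raise ValueError(f"unknown missing policy {policy!r}")


def read_profiles(
    matrix_path, annotation_path, missing_policy: str = "impute"
) -> ProfileMatrix:
    """Read a cohort matrix and its probe annotation from TSV files.

    The returned matrix has its probes sorted genomically regardless of
    the column order of the input, so shuffled inputs yield identical
    objects.
    """
    matrix = pd.read_csv(
        matrix_path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    annotation = pd.read_csv(annotation_path, sep="\t", comment="#")
    probe_map = ProbeMap.from_frame(annotation)
    matrix_probes = set(matrix.columns)
    annotation_probes = set(probe_map.probe_ids)
    if matrix_probes != annotation_probes:
        extra = sorted(matrix_probes - annotation_probes)[:3]
        missing = sorted(annotation_probes - matrix_probes)[:3]
        raise FormatError(
            f"probe sets differ between matrix and annotation "
            f"(matrix-only: {extra}, annotation-only: {missing})"
        )
    matrix = matrix[list(probe_map.probe_ids)]
    matrix = _apply_missing_policy(matrix, missing_policy)
    if matrix.shape[1] != len(probe_map):
        keep = np.isin(probe_map.probe_ids, np.asarray(matrix.columns, dtype=object))
        probe_map = probe_map.subset(np.flatnonzero(keep))
    return ProfileMatrix(list(matrix.index), matrix.to_numpy(dtype=float), probe_map)


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {key}={value}\n" for key, value in provenance.items())


def write_profiles(
    profiles: ProfileMatrix,
    matrix_path,
    annotation_path,
    provenance: dict | None = None,
) -> None:
    """Write the cohort in the same TSV formats :func:`read_profiles` reads."""
    header = _provenance_lines(provenance)
    with open(matrix_path, "w") as fh:
        fh.write(header)
        profiles.to_frame().to_csv(fh, sep="\t")
    with open(annotation_path, "w") as fh:
        fh.write(header)
        profiles.probe_map.to_frame().to_csv(fh, sep="\t", index=False)


def _format_float(value: float) -> str:
    return repr(float(value))


def write_cna_calls(
    calls: Sequence[CNACall], path, format: str = "bed", provenance: dict | None = None
) -> None:
    """Write CNA calls as BED (0-based half-open) or SEG (1-based inclusive)."""
    if format not in ("bed", "seg"):
        raise ValueError(f"unknown CNA call format {format!r}")
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        if format == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tdirection\n")
            for call in calls:
                name = f"{call.node_id or 'cna'}_{call.direction}"
                fh.write(
                    f"{call.chromosome}\t{call.start_bp - 1}\t{call.end_bp}\t"
                    f"{name}\t{_format_float(call.mean_amplitude)}\t{call.direction}\n"
                )
        else:
            fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
            for call in calls:
                fh.write(
                    f"{call.node_id or 'cna'}\t{call.chromosome}\t{call.start_bp}\t"
                    f"{call.end_bp}\t{call.n_probes}\t{_format_float(call.mean_amplitude)}\n"
                )
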