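"""Shared sample-by-site containers and their TSV formats.

Two matrices flow through the pipeline:

* :class:`AlleleCountMatrix` — per sample x site reference/alternative read
  counts (simulator output, or user-supplied sequencing summaries);
* :class:`CallMatrix` — per sample x site genotype state in
  ``{0, 1, ?, -}`` plus the curation marks ``{x, @}`` accepted on input.

Positions are 0-based internally and 1-based in every file written or read,
matching the usual supplementary-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AlleleCountMatrix", "CallMatrix", "VALID_STATES"]

VALID_STATES = frozenset("01?-x@")


def _write_meta(fh, meta: dict):
    for key in sorted(meta):
        fh.write(f"# {key}={meta[key]}\n")


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


@dataclass
class AlleleCountMatrix:
    """Reference/alternative read counts per sample and site."""

    samples: list[str]
    sites: pd.DataFrame  # columns: pos (0-based int), ref, alt alleles
    ref: np.ndarray  # (n_samples, n_sites)
    alt: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.samples), len(self.sites))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got "
                f"{self.ref.shape} / {self.alt.shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def mean_depths(self) -> np.ndarray:
        """Per-sample mean coverage over all sites."""
        return (self.ref + self.alt).mean(axis=1)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            _write_meta(fh, self.meta)
            fh.write("pos\tref\talt\t" + "\t".join(self.samples) + "\n")
            pos1 = self.sites["pos"].to_numpy() + 1
            refs = self.sites["ref"].to_numpy()
            alts = self.sites["alt"].to_numpy()
            for j in range(self.n_sites):
                cells = "\t".join(
                    f"{self.ref[i, j]},{self.alt[i, j]}"
                    for i in range(self.n_samples)
                )
                fh.write(f"{pos1[j]}\t{refs[j]}\t{alts[j]}\t{cells}\n")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountMatrix":
        meta = _read_meta(path)
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        samples = list(df.columns[3:])
        sites = pd.DataFrame(
            {
                "pos": df["pos"].astype(int) - 1,
                "ref": df["ref"],
                "alt": df["alt"],
            }
        )
        n_sites, n_samples = len(df), len(samples)
        ref = np.zeros((n_samples, n_sites), dtype=np.int64)
        alt = np.zeros_like(ref)
        for i, s in enumerate(samples):
            parts = df[s].str.split(",", expand=True).astype(int)
            ref[i] = parts[0].to_numpy()
            alt[i] = parts[1].to_numpy()
        return cls(samples, sites, ref, alt, meta=meta)


@dataclass
class CallMatrix:
    """Genotype states per sample and site (one character per cell)."""

    samples: list[str]
    sites: pd.DataFrame  # columns: pos, ref, alt (alleles), optional name
    states: np.ndarray  # (n_samples, n_sites), dtype <U1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="<U1")
        shape = (len(self.samples), len(self.sites))
        if self.states.shape != shape:
            raise ValueError(f"states must have shape {shape}, got {self.states.shape}")
        bad = set(np.unique(self.states)) - VALID_STATES
        if bad:
            raise ValueError(f"invalid state characters: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "CallMatrix":
        return CallMatrix(
            list(self.samples),
            self.sites.copy(),
            self.states.copy(),
            dict(self.meta),
        )

    def subset_sites(self, mask) -> "CallMatrix":
        mask = np.asarray(mask)
        return CallMatrix(
            list(self.samples),
            self.sites.loc[mask].reset_index(drop=True),
            self.states[:, mask],
            dict(self.meta),
        )

    def to_tsv(self, path):
        with open(path, "w") as fh:
            _write_meta(fh, self.meta)
            fh.write("pos\tref\talt\t" + "\t".join(self.samples) + "\n")
            pos1 = self.sites["pos"].to_numpy() + 1
            refs = self.sites["ref"].to_numpy()
            alts = self.sites["alt"].to_numpy()
            for j in range(self.n_sites):
                cells = "\t".join(self.states[i, j] for i in range(self.n_samples))
                fh.write(f"{pos1[j]}\t{refs[j]}\t{alts[j]}\t{cells}\n")

    @classmethod
    def from_tsv(cls, path) -> "CallMatrix":
        meta = _read_meta(path)
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        samples = list(df.columns[3:])
        sites = pd.DataFrame(
            {
                "pos": df["pos"].astype(int) - 1,
                "ref": df["ref"],
                "alt": df["alt"],
            }
        )
        states = np.array([df[s].to_numpy(dtype="<U1") for s in samples])
        return cls(samples, sites, states, meta=meta)
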