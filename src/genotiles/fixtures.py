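"""Deterministic synthetic inputs for every pipeline path.

The generator emulates the *shapes* that matter to a tiling backend — a
small multi-chromosome genome, an intra-chromosomal contact list with
distance decay and TAD-like block enrichment, a peaky 1D signal with runs of
missing values, and importance-scored annotations — without attempting
realistic Hi-C noise, ligation artifacts, or balancing weights.

Contacts are drawn over bin pairs (i, j) of one chromosome with weight

    w(i, j) = (j - i + 1)^(-alpha) * (beta if i and j share a declared block)

normalized over all intra-chromosomal pairs, so the expected within-block
fraction of a sample has the closed form sum(w | same block) / sum(w)
(:func:`expected_within_block_fraction`).

Everything is a pure function of (spec, seed): identical inputs give
byte-identical files.  The default spec is the "demo genome": two
chromosomes totalling 5 Mb, used by the documentation and example scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .coords import Assembly

__all__ = [
    "FixtureSpec",
    "make_assembly",
    "make_contacts",
    "make_signal",
    "make_annotations",
    "make_demo",
    "expected_within_block_fraction",
]

PathArg = Union[str, Path]


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generator; defaults are the 5 Mb demo genome."""

    seed: int = 0
    chroms: tuple[tuple[str, int], ...] = (("chrA", 3_000_000), ("chrB", 2_000_000))
    # contact model
    n_contacts: int = 10_000
    contact_bin_bp: int = 10_000
    decay_exponent: float = 1.0  # alpha: P(contact) ~ distance^-alpha
    block_enrichment: float = 3.0  # beta: weight boost inside a block
    blocks: tuple[tuple[str, int, int], ...] = (
        ("chrA", 0, 500_000),
        ("chrA", 1_000_000, 1_600_000),
        ("chrB", 200_000, 700_000),
    )
    # signal model
    signal_step_bp: int = 1_000
    baseline: float = 1.0
    peaks: tuple[tuple[str, int, float, int], ...] = (  # (chrom, center, height, sd)
        ("chrA", 1_000_000, 8.0, 50_000),
        ("chrB", 500_000, 5.0, 30_000),
    )
    missing_run_rate: float = 0.02  # per-step probability of starting a gap
    missing_run_mean: float = 5.0  # mean gap length, in steps
    # annotation model
    n_annotations: int = 200
    annotation_min_len: int = 1_000
    annotation_max_len: int = 50_000
    importance_scale: float = 10.0  # exponential distribution scale

    def assembly(self) -> Assembly:
        return Assembly(self.chroms)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent streams per generator so adding one does not shift another
    return np.random.default_rng([spec.seed, stream])


def make_assembly(spec: FixtureSpec, path: Optional[PathArg] = None) -> Assembly:
    """The spec's assembly; optionally also written as a chrom.sizes TSV."""
    assembly = spec.assembly()
    if path is not None:
        assembly.to_chromsizes(path)
    return assembly


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def _pair_weights(spec: FixtureSpec, chrom: str, length: int):
    """Upper-triangle bin pairs of one chromosome and their sampling weights."""
    nb = length // spec.contact_bin_bp
    i, j = np.triu_indices(nb)
    w = ((j - i + 1).astype(np.float64)) ** (-spec.decay_exponent)
    block_id = np.full(nb, -1)
    for b, (bc, bs, be) in enumerate(spec.blocks):
        if bc != chrom:
            continue
        mids = (np.arange(nb) + 0.5) * spec.contact_bin_bp
        block_id[(mids >= bs) & (mids < be)] = b
    same_block = (block_id[i] >= 0) & (block_id[i] == block_id[j])
    w = np.where(same_block, w * spec.block_enrichment, w)
    return i, j, w, same_block


def expected_within_block_fraction(spec: FixtureSpec) -> float:
    """Exact expected fraction of sampled contacts with both ends in one block."""
    total = 0.0
    inside = 0.0
    for chrom, length in spec.chroms:
        _, _, w, same = _pair_weights(spec, chrom, length)
        total += w.sum()
        inside += w[same].sum()
    return inside / total


def make_contacts(spec: FixtureSpec, path: PathArg) -> Path:
    """Sample a contact list and write it as ``chrom1 pos1 chrom2 pos2`` text."""
    rng = _rng(spec, 1)
    per_chrom = []
    totals = []
    for chrom, length in spec.chroms:
        i, j, w, _ = _pair_weights(spec, chrom, length)
        per_chrom.append((chrom, i, j, w))
        totals.append(w.sum())
    totals = np.asarray(totals)
    n_by_chrom = rng.multinomial(spec.n_contacts, totals / totals.sum())
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for (chrom, i, j, w), n in zip(per_chrom, n_by_chrom):
            if n == 0:
                continue
            counts = rng.multinomial(n, w / w.sum())
            pairs = np.repeat(np.arange(len(w)), counts)
            off1 = rng.integers(0, spec.contact_bin_bp, size=len(pairs))
            off2 = rng.integers(0, spec.contact_bin_bp, size=len(pairs))
            p1 = i[pairs] * spec.contact_bin_bp + off1
            p2 = j[pairs] * spec.contact_bin_bp + off2
            for a, b in zip(p1, p2):
                fh.write(f"{chrom}\t{a}\t{chrom}\t{b}\n")
    return path


# ---------------------------------------------------------------------------
# 1D signal
# ---------------------------------------------------------------------------


def make_signal(spec: FixtureSpec, path: PathArg) -> Path:
    """Write a bedGraph: baseline plus Gaussian peaks, with missing runs."""
    rng = _rng(spec, 2)
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, length in spec.chroms:
            n_steps = length // spec.signal_step_bp
            x = (np.arange(n_steps) + 0.5) * spec.signal_step_bp
            values = np.full(n_steps, spec.baseline, dtype=np.float64)
            for pc, center, height, sd in spec.peaks:
                if pc == chrom:
                    values += height * np.exp(-0.5 * ((x - center) / sd) ** 2)
            covered = np.ones(n_steps, dtype=bool)
            if spec.missing_run_rate > 0:
                step = 0
                while step < n_steps:
                    if rng.random() < spec.missing_run_rate:
                        run = rng.geometric(1.0 / spec.missing_run_mean)
                        covered[step : step + run] = False
                        step += run
                    else:
                        step += 1
            for k in range(n_steps):
                if covered[k]:
                    s = k * spec.signal_step_bp
                    fh.write(f"{chrom}\t{s}\t{s + spec.signal_step_bp}\t{values[k]:.6g}\n")
    return path


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def make_annotations(spec: FixtureSpec, path: PathArg) -> Path:
    """Write a 5-column BED with exponential importance scores in column 5."""
    rng = _rng(spec, 3)
    lengths = np.array([l for _, l in spec.chroms], dtype=np.float64)
    chrom_idx = rng.choice(len(spec.chroms), size=spec.n_annotations, p=lengths / lengths.sum())
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for k in range(spec.n_annotations):
            chrom, clen = spec.chroms[chrom_idx[k]]
            span = int(rng.integers(spec.annotation_min_len, spec.annotation_max_len + 1))
            span = min(span, clen)
            start = int(rng.integers(0, clen - span + 1))
            importance = float(rng.exponential(spec.importance_scale))
            fh.write(f"{chrom}\t{start}\t{start + span}\tann{k:04d}\t{importance:.6g}\n")
    return path


def make_demo(out_dir: PathArg, seed: int = 0) -> dict[str, Path]:
    """Write the full demo fixture set into a directory; returns the paths."""
    spec = FixtureSpec(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chromsizes": out / "demo.chrom.sizes",
        "contacts": out / "demo.contacts.txt",
        "signal": out / "demo.signal.bedgraph",
        "annotations": out / "demo.annotations.bed",
    }
    make_assembly(spec, paths["chromsizes"])
    make_contacts(spec, paths["contacts"])
    make_signal(spec, paths["signal"])
    make_annotations(spec, paths["annotations"])
    return paths
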