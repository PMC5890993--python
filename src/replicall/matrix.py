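"""Variant x replicate count matrix.

The statistical test consumes, for every candidate variant, the
variant-supporting read counts in each sample and control replicate plus
the per-position sequencing depths, both split by strand. The candidate
universe is anchored on the sample side: a (position, alt allele) enters
the matrix when its summed support across sample replicates reaches
``min_supporting_reads``. Variants never observed in any sample replicate
are definitionally negative; they contribute only to the multiple-testing
denominator (see :func:`tested_variant_space`) and to the evaluation
denominator, not to matrix rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup import AlleleCounts, PanelRegion, panel_length

#: variant tests per targeted base pair: 3 alternative bases + 1 indel test
TESTS_PER_BP = 4


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True, order=True)
class VariantKey:
    """One (position, alternative allele) hypothesis.

    ``ref`` is the reference base at ``pos`` (the anchor base for
    indels). ``alt`` is a single base for SNVs, ``+SEQ`` for insertions
    and ``-n`` for deletions, following the pileup token convention;
    conversion to VCF anchor-base alleles happens in the VCF writer.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass

    def __post_init__(self) -> None:
        if self.vclass is VariantClass.SNV:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"invalid SNV alleles {self.ref}>{self.alt}")
        elif self.vclass is VariantClass.INS:
            if not (self.alt.startswith("+") and len(self.alt) > 1):
                raise ValueError(f"invalid insertion token {self.alt!r}")
        elif self.vclass is VariantClass.DEL:
            if not (self.alt.startswith("-") and self.alt[1:].isdigit()):
                raise ValueError(f"invalid deletion token {self.alt!r}")

    @property
    def sort_key(self) -> tuple:
        return (self.contig, self.pos, self.vclass is not VariantClass.SNV, self.alt)


def classify_allele(token: str) -> VariantClass:
    if token.startswith("+"):
        return VariantClass.INS
    if token.startswith("-"):
        return VariantClass.DEL
    return VariantClass.SNV


@dataclass
class CountMatrix:
    """Counts and depths for every candidate variant in every replicate.

    All arrays are (n_variants, n_replicates) int64; depths repeat the
    variant position's depth, so variants sharing a position share depth
    rows by value.
    """

    variants: list[VariantKey]
    sample_labels: list[str]
    control_labels: list[str]
    sample_fwd: np.ndarray
    sample_rev: np.ndarray
    control_fwd: np.ndarray
    control_rev: np.ndarray
    sample_depth_fwd: np.ndarray
    sample_depth_rev: np.ndarray
    control_depth_fwd: np.ndarray
    control_depth_rev: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.variants)
        ns, nc = len(self.sample_labels), len(self.control_labels)
        if ns < 1:
            raise ValueError("at least one sample replicate required")
        if nc < 1:
            raise ValueError(
                "control replicates required: the background model is built "
                "from wild-type control libraries"
            )
        if len(set(self.sample_labels) | set(self.control_labels)) != ns + nc:
            raise ValueError("duplicate replicate labels")
        for name in (
            "sample_fwd", "sample_rev", "sample_depth_fwd", "sample_depth_rev",
        ):
            arr = getattr(self, name)
            if arr.shape != (n, ns):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, ns)}")
        for name in (
            "control_fwd", "control_rev", "control_depth_fwd", "control_depth_rev",
        ):
            arr = getattr(self, name)
            if arr.shape != (n, nc):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, nc)}")

    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_counts(self) -> np.ndarray:
        """Strand-pooled sample counts, (n_variants, n_sample)."""
        return self.sample_fwd + self.sample_rev

    @property
    def control_counts(self) -> np.ndarray:
        return self.control_fwd + self.control_rev

    @property
    def sample_depths(self) -> np.ndarray:
        return self.sample_depth_fwd + self.sample_depth_rev

    @property
    def control_depths(self) -> np.ndarray:
        return self.control_depth_fwd + self.control_depth_rev

    def position_depth_matrix(self) -> np.ndarray:
        """Depth per unique position x replicate (samples then controls).

        Used for size-factor estimation: rows are unique (contig, pos)
        so positions carrying several candidate alleles are not
        double-counted.
        """
        seen: dict[tuple[str, int], int] = {}
        rows = []
        for i, v in enumerate(self.variants):
            key = (v.contig, v.pos)
            if key not in seen:
                seen[key] = len(rows)
                rows.append(i)
        idx = np.asarray(rows, dtype=int)
        return np.hstack(
            [
                self.sample_depth_fwd[idx] + self.sample_depth_rev[idx],
                self.control_depth_fwd[idx] + self.control_depth_rev[idx],
            ]
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "contig": [v.contig for v in self.variants],
            "pos": [v.pos for v in self.variants],
            "ref": [v.ref for v in self.variants],
            "alt": [v.alt for v in self.variants],
            "vclass": [v.vclass.value for v in self.variants],
        }
        for j, lab in enumerate(self.sample_labels):
            cols[f"sample:{lab}:count_fwd"] = self.sample_fwd[:, j]
            cols[f"sample:{lab}:count_rev"] = self.sample_rev[:, j]
            cols[f"sample:{lab}:depth_fwd"] = self.sample_depth_fwd[:, j]
            cols[f"sample:{lab}:depth_rev"] = self.sample_depth_rev[:, j]
        for j, lab in enumerate(self.control_labels):
            cols[f"control:{lab}:count_fwd"] = self.control_fwd[:, j]
            cols[f"control:{lab}:count_rev"] = self.control_rev[:, j]
            cols[f"control:{lab}:depth_fwd"] = self.control_depth_fwd[:, j]
            cols[f"control:{lab}:depth_rev"] = self.control_depth_rev[:, j]
        return pd.DataFrame(cols)

    def to_tsv(self, path_or_stream) -> None:
        self.to_frame().to_csv(path_or_stream, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_stream) -> "CountMatrix":
        df = pd.read_csv(path_or_stream, sep="\t")
        variants = [
            VariantKey(r.contig, int(r.pos), r.ref, r.alt, VariantClass(r.vclass))
            for r in df.itertuples()
        ]
        sample_labels, control_labels = [], []
        for c in df.columns:
            parts = c.split(":")
            if len(parts) == 3 and parts[2] == "count_fwd":
                (sample_labels if parts[0] == "sample" else control_labels).append(parts[1])

        def grab(cond: str, labels: list[str], what: str) -> np.ndarray:
            return df[[f"{cond}:{lab}:{what}" for lab in labels]].to_numpy(dtype=np.int64)

        return cls(
            variants=variants,
            sample_labels=sample_labels,
            control_labels=control_labels,
            sample_fwd=grab("sample", sample_labels, "count_fwd"),
            sample_rev=grab("sample", sample_labels, "count_rev"),
            control_fwd=grab("control", control_labels, "count_fwd"),
            control_rev=grab("control", control_labels, "count_rev"),
            sample_depth_fwd=grab("sample", sample_labels, "depth_fwd"),
            sample_depth_rev=grab("sample", sample_labels, "depth_rev"),
            control_depth_fwd=grab("control", control_labels, "depth_fwd"),
            control_depth_rev=grab("control", control_labels, "depth_rev"),
        )


def tested_variant_space(panel: Sequence[PanelRegion]) -> int:
    """Number of variant hypotheses a panel supports: bp x (3 SNV + 1 indel)."""
    return panel_length(panel) * TESTS_PER_BP


def build_matrix(
    sample_pileups: Sequence[Iterable[AlleleCounts]],
    control_pileups: Sequence[Iterable[AlleleCounts]],
    panel: Sequence[PanelRegion] | None = None,
    min_supporting_reads: int = 1,
    sample_labels: Sequence[str] | None = None,
    control_labels: Sequence[str] | None = None,
) -> CountMatrix:
    """Assemble the variant x replicate matrix from per-replicate pileups.

    The variant universe is every (position, alt) whose summed support
    across sample replicates is >= ``min_supporting_reads``; counts and
    depths are then filled for every replicate of both conditions, with
    zeros where a replicate shows no support or no coverage.
    """
    if len(sample_pileups) < 1:
        raise ValueError("at least one sample replicate required")
    if len(control_pileups) < 1:
        raise ValueError(
            "no control replicates supplied; the test needs wild-type "
            "control libraries to model the error background"
        )
    if min_supporting_reads < 1:
        raise ValueError("min_supporting_reads must be >= 1")
    sample_labels = list(sample_labels or (f"sample_{j+1}" for j in range(len(sample_pileups))))
    control_labels = list(control_labels or (f"control_{j+1}" for j in range(len(control_pileups))))
    if len(set(sample_labels)) != len(sample_labels) or len(set(control_labels)) != len(control_labels):
        raise ValueError("duplicate replicate labels")

    from .pileup import in_panel

    def index(pileup: Iterable[AlleleCounts]) -> dict[tuple[str, int], AlleleCounts]:
        out = {}
        for ac in pileup:
            if panel is not None and not in_panel(panel, ac.contig, ac.pos):
                continue
            out[(ac.contig, ac.pos)] = ac
        return out

    s_idx = [index(p) for p in sample_pileups]
    c_idx = [index(p) for p in control_pileups]

    support: dict[tuple[str, int, str], tuple[str, int]] = {}
    for idx in s_idx:
        for (contig, pos), ac in idx.items():
            for token, cnt in list(ac.fwd.items()) + list(ac.rev.items()):
                key = (contig, pos, token)
                ref, total = support.get(key, (ac.ref, 0))
                support[key] = (ref, total + cnt)

    variants = sorted(
        (
            VariantKey(contig, pos, ref, token, classify_allele(token))
            for (contig, pos, token), (ref, total) in support.items()
            if total >= min_supporting_reads
        ),
        key=lambda v: v.sort_key,
    )

    n, ns, nc = len(variants), len(s_idx), len(c_idx)

    def fill(indexes: list[dict]) -> tuple[np.ndarray, ...]:
        cf = np.zeros((n, len(indexes)), dtype=np.int64)
        cr = np.zeros_like(cf)
        df_ = np.zeros_like(cf)
        dr = np.zeros_like(cf)
        for j, idx in enumerate(indexes):
            for i, v in enumerate(variants):
                ac = idx.get((v.contig, v.pos))
                if ac is None:
                    continue
                cf[i, j] = ac.fwd.get(v.alt, 0)
                cr[i, j] = ac.rev.get(v.alt, 0)
                df_[i, j] = ac.depth_fwd
                dr[i, j] = ac.depth_rev
        return cf, cr, df_, dr

    s_cf, s_cr, s_df, s_dr = fill(s_idx)
    c_cf, c_cr, c_df, c_dr = fill(c_idx)
    return CountMatrix(
        variants=variants,
        sample_labels=sample_labels,
        control_labels=control_labels,
        sample_fwd=s_cf,
        sample_rev=s_cr,
        control_fwd=c_cf,
        control_rev=c_cr,
        sample_depth_fwd=s_df,
        sample_depth_rev=s_dr,
        control_depth_fwd=c_df,
        control_depth_rev=c_dr,
    )
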