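"""Core domain types: variants, call states and the genotype matrix.

All coordinates are 1-based (VCF convention). A genotype matrix stores one
call state per sample x variant cell; the four states are exhaustive and
mutually exclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CallState",
    "Variant",
    "GenotypeMatrix",
    "KnownVariantList",
    "PipelineError",
    "ConfigError",
    "FormatError",
    "GenerationError",
    "natural_key",
]

_VALID_ALLELES = frozenset("ACGT")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PipelineError):
    """Invalid configuration or parameters."""


class FormatError(PipelineError):
    """Malformed input file."""


class GenerationError(PipelineError):
    """Synthetic data generation could not satisfy its constraints."""


class CallState(IntEnum):
    """State of one haploid call at one site."""

    ANCESTRAL = 0
    DERIVED = 1
    MISSING = 2
    AMBIGUOUS = 3


def natural_key(label: str) -> tuple:
    """Sort key treating embedded digit runs numerically (Z9 before Z10)."""
    parts = re.split(r"(\d+)", label)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Variant:
    """One biallelic Y-chromosome site with fixed ancestral orientation.

    Parameters
    ----------
    contig : str
        Reference contig name (normally ``"chrY"``).
    position : int
        1-based position on the contig.
    ancestral_allele, derived_allele : str
        Single-base alleles; must differ.
    name : str, optional
        Marker name (e.g. ``"DF27"``); defaults to a coordinate label.
    known : bool
        Whether the variant matches an entry of a known-variant list.
    rs_id : str, optional
        dbSNP identifier, if any.
    """

    contig: str
    position: int
    ancestral_allele: str
    derived_allele: str
    name: Optional[str] = None
    known: bool = False
    rs_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ConfigError(f"position must be >= 1, got {self.position}")
        if self.ancestral_allele not in _VALID_ALLELES:
            raise ConfigError(f"bad ancestral allele {self.ancestral_allele!r}")
        if self.derived_allele not in _VALID_ALLELES:
            raise ConfigError(f"bad derived allele {self.derived_allele!r}")
        if self.ancestral_allele == self.derived_allele:
            raise ConfigError(
                f"ancestral and derived alleles are both {self.derived_allele!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.contig, self.position)

    @property
    def label(self) -> str:
        """Display name: the marker name, else a coordinate-based label."""
        if self.name:
            return self.name
        return f"{self.contig}:{self.position}{self.ancestral_allele}>{self.derived_allele}"

    def with_name(self, name: str, known: bool = True) -> "Variant":
        return Variant(
            contig=self.contig,
            position=self.position,
            ancestral_allele=self.ancestral_allele,
            derived_allele=self.derived_allele,
            name=name,
            known=known,
            rs_id=self.rs_id,
        )


class GenotypeMatrix:
    """Samples x variants call-state matrix.

    Cells are stored as an ``int8`` array of :class:`CallState` values. An
    optional allele-depth array (``ad``, shape ``(n_samples, n_variants, 2)``
    holding ancestral/derived read counts) lets writers emit AD and readers
    recompute ambiguity.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[Variant],
        calls: np.ndarray,
        populations: Optional[dict[str, str]] = None,
        ad: Optional[np.ndarray] = None,
    ) -> None:
        self.samples = list(samples)
        self.variants = list(variants)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.variants)):
            raise ConfigError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ConfigError("sample ids are not unique")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ConfigError("(contig, position) keys are not unique")
        if calls.size and (calls.min() < 0 or calls.max() > 3):
            raise ConfigError("calls contain values outside the CallState range")
        self.calls = calls
        self.populations = dict(populations) if populations else {}
        if ad is not None:
            ad = np.asarray(ad)
            if ad.shape != (len(self.samples), len(self.variants), 2):
                raise ConfigError(f"ad shape {ad.shape} inconsistent with matrix")
        self.ad = ad
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v.key: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def variant_index(self, variant: Variant) -> int:
        return self._variant_index[variant.key]

    def find_variant(self, name_or_key: str) -> Optional[Variant]:
        """Look a variant up by marker name or ``contig:position`` string."""
        for v in self.variants:
            if v.name == name_or_key:
                return v
        if ":" in name_or_key:
            contig, _, pos = name_or_key.rpartition(":")
            try:
                idx = self._variant_index.get((contig, int(pos)))
            except ValueError:
                return None
            if idx is not None:
                return self.variants[idx]
        return None

    def column(self, variant: Variant) -> np.ndarray:
        return self.calls[:, self.variant_index(variant)]

    def state(self, sample: str, variant: Variant) -> CallState:
        return CallState(self.calls[self._sample_index[sample], self.variant_index(variant)])

    def samples_in_state(self, variant: Variant, state: CallState) -> set[str]:
        col = self.column(variant)
        return {self.samples[i] for i in np.nonzero(col == state)[0]}

    def state_counts(self) -> dict[CallState, int]:
        return {s: int(np.count_nonzero(self.calls == s)) for s in CallState}

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in keep]
        ad = self.ad[idx] if self.ad is not None else None
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.variants,
            self.calls[idx],
            populations={s: p for s, p in self.populations.items() if s in set(keep)},
            ad=ad,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class KnownVariantList:
    """Set of known markers keyed by (contig, position, derived allele)."""

    entries: dict[tuple[str, int, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.entries

    def name_of(self, variant: Variant) -> Optional[str]:
        return self.entries.get(
            (variant.contig, variant.position, variant.derived_allele)
        )
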