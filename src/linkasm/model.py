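"""Closed-form library model for barcoded linked-read data.

A linked-read library partitions long DNA molecules across ~10^6 barcoded
droplets and sequences each molecule shallowly with short read pairs.  The
quantities that govern assembly power are the number of molecules per
partition (M), the number of read pairs per molecule (LPM), the per-molecule
read depth, and the overall genome coverage.  This module computes those
expectations from the physical library parameters, so simulations and real
designs can be sanity-checked against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: double-stranded DNA bases per nanogram (650 g/mol per bp)
BASES_PER_NG = 6.022e23 / 650.0 / 1e9


@dataclass(frozen=True)
class MoleculeLengthDist:
    """Input molecule length distribution.

    kind="fixed" puts all mass at `mean` (the worked-model convention);
    kind="lognormal" is parameterised by its length-weighted mean (LWM,
    sum(l^2)/sum(l)) and the log-space sigma, which better matches the
    broad length spectra of real high-molecular-weight preps.
    """

    kind: str = "fixed"
    mean: float = 50_000.0  # bases; for lognormal this is the LWM target
    sigma: float = 0.6

    def __post_init__(self):
        if self.kind not in ("fixed", "lognormal"):
            raise ValueError(f"unknown molecule length distribution {self.kind!r}")
        if self.mean <= 0:
            raise ValueError("molecule length must be positive")

    @property
    def mu(self) -> float:
        # lognormal: LWM = exp(mu + 1.5 sigma^2)
        return math.log(self.mean) - 1.5 * self.sigma**2

    def expectation(self) -> float:
        """Mean molecule length."""
        if self.kind == "fixed":
            return self.mean
        return math.exp(self.mu + self.sigma**2 / 2.0)

    def lwm(self) -> float:
        """Length-weighted mean, sum(l^2)/sum(l)."""
        return self.mean

    def sample(self, rng, n: int):
        import numpy as np

        if self.kind == "fixed":
            return np.full(n, self.mean)
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass
class LibraryModel:
    """Physical parameters of a linked-read library."""

    genome_size: float = 3.2e9
    n_partitions: int = 1_000_000
    molecules_per_partition: float | None = 10.0  # if None, derived from mass
    loaded_mass_ng: float | None = None
    recovery_fraction: float = 0.40
    molecule_length: MoleculeLengthDist = field(default_factory=MoleculeLengthDist)
    total_reads: float = 1.2e9  # individual reads, not pairs
    read_length: int = 150
    barcode_length: int = 16
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if self.n_partitions <= 0:
            raise ValueError("partition count must be positive")
        if not (0.0 < self.recovery_fraction <= 1.0):
            raise ValueError("recovery fraction must be in (0, 1]")
        if self.total_reads < 0:
            raise ValueError("total reads must be non-negative")
        if self.read_length <= self.barcode_length:
            raise ValueError("read length must exceed barcode length")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error rate must be in [0, 1)")

    @classmethod
    def desk(
        cls,
        genome_size: float,
        coverage: float = 56.25,
        molecules_per_partition: float | None = None,
        molecule_length: MoleculeLengthDist | None = None,
        read_length: int = 150,
        **kw,
    ) -> "LibraryModel":
        """Scale the standard human design down to a small genome.

        Keeps the per-molecule statistics of the full-scale design (molecule
        length, read pairs per molecule, per-molecule depth) and shrinks the
        partition count so that the requested genome read coverage holds.

        Unless given, the partition count stays at the device's ~10^6 and
        molecules-per-partition shrinks with the loaded mass -- the
        small-genome workflow (less DNA, same chip).  At full scale a
        partition holds ~10 molecules yet samples only ~0.016% of the
        genome, so same-barcode molecules essentially never fall near one
        another; keeping 10^6 partitions reproduces that collision regime
        at any genome size, whereas 10 molecules per partition on a
        megabase genome would make same-barcode collisions the norm and
        corrupt the molecule signal barcodes are meant to carry.
        """
        dist = molecule_length or MoleculeLengthDist()
        total_reads = coverage * genome_size / read_length
        # per-molecule depth of the reference design: 60 pairs on a 50 kb
        # molecule at 2x150 -> 0.36x; keep it fixed while scaling.
        lpm_ref = 0.36 * dist.expectation() / (2.0 * read_length)
        total_molecules = (total_reads / 2.0) / lpm_ref
        if molecules_per_partition is None:
            n_partitions = 1_000_000
            molecules_per_partition = total_molecules / n_partitions
        else:
            n_partitions = max(1, round(total_molecules / molecules_per_partition))
        return cls(
            genome_size=genome_size,
            n_partitions=n_partitions,
            molecules_per_partition=molecules_per_partition,
            molecule_length=dist,
            total_reads=total_reads,
            read_length=read_length,
            **kw,
        )


@dataclass(frozen=True)
class ModelExpectations:
    molecules_per_partition: float
    dna_per_partition: float  # bases
    read_pairs_per_molecule: float  # LPM
    per_molecule_depth: float  # x
    genome_coverage: float  # x
    read_spacing: float  # mean distance between read pairs on a molecule, bases


def model_calculator(model: LibraryModel) -> ModelExpectations:
    """Expected library statistics from the physical model.

    M, the molecule count per partition, is either given directly or derived
    from the loaded mass: of the DNA loaded, only `recovery_fraction`
    contributes to the library, and the surviving mass is spread evenly over
    the partitions.  LPM is the read-pair budget divided over all molecules,
    and the per-molecule depth follows from the read footprint on a molecule
    of mean length.
    """
    model.validate()
    mean_len = model.molecule_length.expectation()
    if model.molecules_per_partition is not None:
        m = float(model.molecules_per_partition)
    else:
        if model.loaded_mass_ng is None:
            raise ValueError("need molecules_per_partition or loaded_mass_ng")
        m = (
            model.loaded_mass_ng
            * model.recovery_fraction
            * BASES_PER_NG
            / (mean_len * model.n_partitions)
        )
    dna_per_partition = m * mean_len
    total_molecules = model.n_partitions * m
    lpm = (model.total_reads / 2.0) / total_molecules if total_molecules > 0 else 0.0
    depth = lpm * 2.0 * model.read_length / mean_len
    coverage = model.total_reads * model.read_length / model.genome_size
    spacing = mean_len / lpm if lpm > 0 else math.inf
    return ModelExpectations(
        molecules_per_partition=m,
        dna_per_partition=dna_per_partition,
        read_pairs_per_molecule=lpm,
        per_molecule_depth=depth,
        genome_coverage=coverage,
        read_spacing=spacing,
    )
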