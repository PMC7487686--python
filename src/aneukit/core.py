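"""Shared domain types and chromosome naming conventions.

Chromosomes follow the budding-yeast convention ``chrI`` .. ``chrXVI`` plus
the mitochondrial genome ``chrMito``. A strain's karyotype is the
per-chromosome copy-number vector relative to a haploid base ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MITO_CHROMOSOME = "chrMito"

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def chromosome_name(index: int) -> str:
    """Roman-numeral chromosome name for a 1-based index (1 -> 'chrI')."""
    if not 1 <= index <= len(_ROMAN):
        raise ValueError(f"chromosome index out of range: {index}")
    return f"chr{_ROMAN[index - 1]}"


def nuclear_chromosomes(n: int = 16) -> list[str]:
    """The first ``n`` nuclear chromosome names."""
    return [chromosome_name(i) for i in range(1, n + 1)]


@dataclass(frozen=True)
class Karyotype:
    """Per-chromosome integer copy numbers for one strain.

    Parameters
    ----------
    strain_id
        Label for the strain (e.g. ``"D2"`` for a chromosome-II disome).
    copy_number
        Mapping chromosome name -> copies carried (all >= 1).
    base_ploidy
        Copy number of a non-amplified chromosome; 1 for haploids.
    """

    strain_id: str
    copy_number: dict[str, int] = field(default_factory=dict)
    base_ploidy: int = 1

    def __post_init__(self) -> None:
        if self.base_ploidy < 1:
            raise ValueError("base_ploidy must be >= 1")
        for chrom, cn in self.copy_number.items():
            if int(cn) != cn or cn < 1:
                raise ValueError(f"copy number for {chrom} must be a positive integer, got {cn}")

    def copies(self, chromosome: str) -> int:
        try:
            return self.copy_number[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} absent from karyotype of {self.strain_id}") from None

    @property
    def duplicated(self) -> set[str]:
        """Chromosomes carried above base ploidy."""
        return {c for c, n in self.copy_number.items() if n > self.base_ploidy}

    @property
    def is_euploid(self) -> bool:
        return not self.duplicated

    @classmethod
    def euploid(cls, strain_id: str = "WT", chromosomes: list[str] | None = None,
                base_ploidy: int = 1) -> "Karyotype":
        chroms = chromosomes if chromosomes is not None else nuclear_chromosomes()
        return cls(strain_id, {c: base_ploidy for c in chroms}, base_ploidy)

    @classmethod
    def disome(cls, strain_id: str, duplicated: list[str] | tuple[str, ...] | set[str],
               chromosomes: list[str] | None = None) -> "Karyotype":
        """Haploid karyotype with the given chromosomes at copy 2."""
        chroms = chromosomes if chromosomes is not None else nuclear_chromosomes()
        cn = {c: 2 if c in set(duplicated) else 1 for c in chroms}
        return cls(strain_id, cn, base_ploidy=1)


def aneuploid_panel() -> dict[str, Karyotype]:
    """The six-strain disome panel studied here, keyed by strain label.

    "D1/2/8" denotes a haploid carrying chromosomes I, II and VIII in
    duplicate; the labels follow the disome-number convention.
    """
    spec = {
        "D2": ["chrII"],
        "D1/2": ["chrI", "chrII"],
        "D1/2/8": ["chrI", "chrII", "chrVIII"],
        "D1/2/8/11": ["chrI", "chrII", "chrVIII", "chrXI"],
        "D1/8": ["chrI", "chrVIII"],
        "D13": ["chrXIII"],
    }
    return {name: Karyotype.disome(name, dups) for name, dups in spec.items()}
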