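"""Peptide records and exchangeable-site bookkeeping.

Backbone amide deuterium uptake is counted over "exchangeable" residues:
prolines carry no backbone amide hydrogen, and the first ``n_term_excluded``
residues of a digested peptide (default 2: the N-terminal residue has no
measured amide, and the second back-exchanges faster than any practical dead
time) are excluded from the count.
"""

from __future__ import annotations

from dataclasses import dataclass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_N_TERM_EXCLUDED = 2


@dataclass(frozen=True)
class PeptideRecord:
    """A digested peptide mapped onto its parent protein.

    start/end are 1-based inclusive residue indices on the parent sequence.
    """

    sequence: str
    start: int
    end: int
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence is empty")
        bad = [(i + 1, aa) for i, aa in enumerate(self.sequence) if aa not in STANDARD_AA]
        if bad:
            pos, aa = bad[0]
            raise ValueError(f"unknown residue code {aa!r} at peptide position {pos}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("residue span does not match sequence length")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def peptide_id(self) -> str:
        return f"{self.sequence[0]}{self.start}-{self.sequence[-1]}{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


def exchangeable_positions(
    peptide: PeptideRecord | str, n_term_excluded: int = DEFAULT_N_TERM_EXCLUDED
) -> list[int]:
    """1-based peptide positions whose amide uptake is counted.

    Excludes the first ``n_term_excluded`` positions and every proline.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if len(seq) < n_term_excluded:
        raise ValueError("sequence shorter than the N-terminal exclusion")
    return [i + 1 for i, aa in enumerate(seq) if i + 1 > n_term_excluded and aa != "P"]


def count_exchangeable(
    peptide: PeptideRecord | str, n_term_excluded: int = DEFAULT_N_TERM_EXCLUDED
) -> int:
    """Number of exchangeable backbone amides of a digested peptide."""
    return len(exchangeable_positions(peptide, n_term_excluded))
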