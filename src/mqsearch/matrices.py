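"""Amino-acid exchange matrices used for column conservation scoring.

The motif finder scores every alignment column by the average pairwise
exchange score of the residues observed there.  Any symmetric 20x20 matrix
can be supplied; the default is the Dayhoff-type PAM250 log-odds matrix
shipped with Biopython, on which a score of ``1.0`` or more marks a
favourable substitution (e.g. A/S scores 1, I/L scores 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Default conservation threshold on the PAM250 matrix: an average pairwise
#: exchange score at or above this marks a column as favourably substituted.
DEFAULT_CONSERVATION_THRESHOLD = 1.0

#: Score contributed by any residue pair involving a gap.  Far below every
#: PAM250 entry (minimum -8) so a gapped pair can never look conserved.
DEFAULT_GAP_SCORE = -10.0


@dataclass(frozen=True)
class ExchangeMatrix:
    """A symmetric amino-acid exchange (substitution) matrix.

    Parameters
    ----------
    name:
        Label reported in outputs (e.g. ``"PAM250"``).
    scores:
        Mapping of ordered residue pairs to scores.  Construction via
        :meth:`from_pairs` or :meth:`pam250` guarantees symmetry and full
        coverage of the 20 standard amino acids.
    """

    name: str
    scores: dict = field(repr=False)

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"no exchange score for residue pair ({a!r}, {b!r})") from None

    def covers(self, residue: str) -> bool:
        return (residue, residue) in self.scores

    @classmethod
    def from_pairs(cls, name: str, pair_scores: dict) -> "ExchangeMatrix":
        """Build a matrix from ``{(a, b): score}`` entries, symmetrising."""
        scores: dict = {}
        for (a, b), s in pair_scores.items():
            s = float(s)
            prev = scores.get((a, b))
            if prev is not None and prev != s:
                raise ValueError(f"conflicting scores for pair ({a}, {b}): {prev} vs {s}")
            scores[(a, b)] = s
            scores[(b, a)] = s
        return cls(name=name, scores=scores)

    @classmethod
    def pam250(cls) -> "ExchangeMatrix":
        """The Dayhoff PAM250 log-odds matrix (Biopython's copy)."""
        mat = substitution_matrices.load("PAM250")
        pairs = {
            (a, b): float(mat[a, b])
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        }
        return cls.from_pairs("PAM250", pairs)


def default_matrix() -> ExchangeMatrix:
    return ExchangeMatrix.pam250()
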