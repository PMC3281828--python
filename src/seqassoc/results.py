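"""Result containers shared by all association tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PermutationNull:
    """Null statistic values from label-shuffling permutations.

    Labels are permuted over individuals; each individual's genotype row,
    including its missingness pattern, stays fixed — the exchangeability
    that makes permutation inference valid under MCAR missingness.
    """

    values: np.ndarray
    seed: int | None = None
    scheme: str = "case-control label shuffle"

    @property
    def m(self) -> int:
        return len(self.values)


@dataclass
class TestResult:
    """Outcome of one locus-wide association test.

    ``p_value`` is None for pure decision tests; permutation p-values are
    bounded below by 1/(m+1). ``valid`` is False when the test could not be
    performed (with ``reason`` saying why), e.g. CMC with effective
    denominator df <= 4 or no complete individuals.
    """

    method: str
    statistic: float
    p_value: float | None
    n_variants: int = 0
    m: int | None = None
    valid: bool = True
    reason: str = ""
    extras: dict = field(default_factory=dict)
    permutation_null: PermutationNull | None = None

    def rejects(self, alpha: float) -> bool:
        """Reject at level alpha (p <= alpha); decision tests consult extras."""
        if not self.valid:
            raise ValueError(f"invalid result: {self.reason}")
        if self.p_value is not None:
            return self.p_value <= alpha
        return bool(self.extras["reject"])
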