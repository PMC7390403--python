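"""Microhomology-mediated end-joining (MMEJ) deletion prediction.

After a double-strand break, resection can expose short direct repeats on
either side of the cut; annealing them and religating deletes the intervening
sequence plus one repeat copy.  At repeat-rich cut sites this biases repair
toward a small set of stereotyped deletions — at the exon 6 di-arginine loop
site the 3/9/12-bp in-frame products that dominate the observed allele
spectrum.

``enumerate_mmej`` lists every deletion product supported by a flanking
direct repeat of at least ``min_microhomology`` bases whose deletion interval
can be placed (shifting within the repeat) to contain or abut the cut.
Products are deduplicated by product sequence, since distinct repeat pairs
can imply the same repaired molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


class MMEJError(ValueError):
    pass


@dataclass(frozen=True)
class MMEJProduct:
    """One predicted deletion product.

    ``deleted_interval`` is the 3'-most equivalent placement of the deletion;
    ``placements`` is the full contiguous run of start offsets that yield the
    same product sequence (the repeat-induced ambiguity of the junction).
    ``repeat_pairs`` records every contributing ``(left_start, right_start,
    length)`` direct repeat.  ``weight`` is a relative likelihood used only by
    the repair simulator, never by the annotator.
    """

    repeat_seq: str
    left_repeat_interval: tuple[int, int]
    right_repeat_interval: tuple[int, int]
    deleted_interval: tuple[int, int]
    deletion_size: int
    in_frame: bool
    product_sequence: str
    weight: float = 0.0
    placements: tuple[int, ...] = field(default=())
    repeat_pairs: tuple[tuple[int, int, int], ...] = field(default=())

    @property
    def microhomology_length(self) -> int:
        return len(self.repeat_seq)


def _placement_run(seq: str, a: int, d: int) -> tuple[int, int]:
    """Contiguous run [lo, hi] of start offsets whose d-bp deletion equals
    deleting [a, a+d): extend while the base leaving the junction matches the
    base entering it."""
    lo = a
    while lo > 0 and seq[lo - 1] == seq[lo - 1 + d]:
        lo -= 1
    hi = a
    while hi + d < len(seq) and seq[hi] == seq[hi + d]:
        hi += 1
    return lo, hi


def _common_extension(seq: str, i: int, j: int) -> int:
    """Length of the longest common prefix of seq[i:] and seq[j:]."""
    m = 0
    n = len(seq)
    while j + m < n and seq[i + m] == seq[j + m]:
        m += 1
    return m


def enumerate_mmej(
    sequence: str,
    cut: int,
    min_microhomology: int = 2,
    max_deletion: int = 30,
    *,
    weight_scale: float = 20.0,
) -> list[MMEJProduct]:
    """Enumerate MMEJ deletion products around an inter-base cut position.

    Every pair of identical substrings of length >= ``min_microhomology``
    whose start distance ``d`` is <= ``max_deletion`` induces the deletion of
    ``d`` bases.  A product is kept when some equivalent placement of its
    deletion interval contains or abuts the cut.  Products are deduplicated
    by ``product_sequence``; each carries ``in_frame = (d % 3 == 0)`` and a
    simulator weight ``mh_length * exp(-d / weight_scale)``, normalised over
    the returned products.
    """
    n = len(sequence)
    if not 0 <= cut <= n:
        raise MMEJError(f"cut {cut} outside sequence of length {n}")
    if min_microhomology < 1:
        raise MMEJError("min_microhomology must be >= 1")

    by_product: dict[str, dict] = {}
    for i in range(n):
        for j in range(i + 1, min(i + max_deletion, n - min_microhomology) + 1):
            m = _common_extension(sequence, i, j)
            if m < min_microhomology:
                continue
            d = j - i
            lo, hi = _placement_run(sequence, i, d)
            if hi + d < cut or lo > cut:  # no placement contains or abuts the cut
                continue
            product = sequence[:i] + sequence[j:]
            entry = by_product.setdefault(
                product,
                {
                    "d": d,
                    "lo": lo,
                    "hi": hi,
                    "pairs": [],
                    "best": None,  # (mh_len, left_start) of the longest repeat
                },
            )
            entry["pairs"].append((i, j, m))
            if entry["best"] is None or m > entry["best"][0]:
                entry["best"] = (m, i)

    products: list[MMEJProduct] = []
    for product, entry in by_product.items():
        d = entry["d"]
        mh_len, left = entry["best"]
        right = left + d
        products.append(
            MMEJProduct(
                repeat_seq=sequence[left : left + mh_len],
                left_repeat_interval=(left, left + mh_len),
                right_repeat_interval=(right, right + mh_len),
                deleted_interval=(entry["hi"], entry["hi"] + d),
                deletion_size=d,
                in_frame=(d % 3 == 0),
                product_sequence=product,
                weight=mh_len * math.exp(-d / weight_scale),
                placements=tuple(range(entry["lo"], entry["hi"] + 1)),
                repeat_pairs=tuple(sorted(entry["pairs"])),
            )
        )

    total = sum(p.weight for p in products)
    if total > 0:
        products = [replace(p, weight=p.weight / total) for p in products]
    products.sort(key=lambda p: (p.deletion_size, p.deleted_interval, p.product_sequence))
    return products
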