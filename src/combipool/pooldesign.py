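"""Design of assembly pools and combinatorial pools.

Two-stage pooled sequencing cuts library costs: strains are first mixed
into a few deeply-sequenced *assembly pools* (only distinct genera
together, so near-identical regions do not co-assemble), then
redistributed into *combinatorial pools* such that each strain's binary
pattern of presence/absence across those pools — its signature — is
unique within its assembly pool.  Contigs are later attributed to
strains by correlating per-pool coverage against these signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, DesignInfeasibleError, SchemaError


@dataclass(frozen=True)
class StrainRecord:
    """One strain of the sequencing collection."""

    strain_id: str
    genus: str
    species: str = ""
    assembly_pool_id: int = 0

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise SchemaError("strain_id must be nonempty")
        if not self.genus:
            raise SchemaError(f"strain {self.strain_id}: genus must be nonempty")


@dataclass
class SignatureMatrix:
    """Binary strain-presence pattern over combinatorial pools.

    One row per strain; entry (s, p) is 1 iff strain s's DNA is present
    in combinatorial pool p.  Rows must be nonzero and pairwise distinct
    among strains sharing an assembly pool.
    """

    strain_ids: list[str]
    matrix: np.ndarray  # shape (n_strains, n_pools), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.strain_ids):
            raise SchemaError("signature matrix shape does not match strain ids")
        if not np.isin(self.matrix, (0, 1)).all():
            raise SchemaError("signature entries must be 0/1")

    @property
    def n_pools(self) -> int:
        return self.matrix.shape[1]

    def row(self, strain_id: str) -> np.ndarray:
        return self.matrix[self.strain_ids.index(strain_id)]

    def subset(self, strain_ids: list[str]) -> "SignatureMatrix":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return SignatureMatrix(list(strain_ids), self.matrix[idx].copy())


@dataclass
class ValidationReport:
    """Report-only check of a signature design; never raises."""

    duplicate_rows: list[tuple[str, str]] = field(default_factory=list)
    zero_rows: list[str] = field(default_factory=list)
    unknown_strains: list[str] = field(default_factory=list)
    min_hamming: int | None = None

    @property
    def ok(self) -> bool:
        return not (self.duplicate_rows or self.zero_rows or self.unknown_strains)


def assign_assembly_pools(
    strains: list[StrainRecord], n_pools: int
) -> dict[str, int]:
    """Distribute strains over assembly pools so no genus is split within a pool.

    Pools are numbered 1..n_pools.  Genera are placed largest-first, each
    genus going to its currently least-loaded pools, which keeps pool sizes
    balanced within +/-1 whenever the genus constraint allows.

    Raises
    ------
    DesignInfeasibleError
        If any genus has more member strains than there are pools.
    """
    if n_pools < 1:
        raise DesignInfeasibleError("need at least one assembly pool")
    by_genus: dict[str, list[StrainRecord]] = {}
    seen: set[str] = set()
    for s in strains:
        if s.strain_id in seen:
            raise SchemaError(f"duplicate strain_id {s.strain_id!r}")
        seen.add(s.strain_id)
        by_genus.setdefault(s.genus, []).append(s)
    for genus, members in by_genus.items():
        if len(members) > n_pools:
            raise DesignInfeasibleError(
                f"genus {genus!r} has {len(members)} strains but only "
                f"{n_pools} assembly pools are available"
            )
    loads = {p: 0 for p in range(1, n_pools + 1)}
    assignment: dict[str, int] = {}
    # Largest genera first (classic LPT greedy); ties broken by name for
    # determinism.
    for genus in sorted(by_genus, key=lambda g: (-len(by_genus[g]), g)):
        members = by_genus[genus]
        chosen = sorted(loads, key=lambda p: (loads[p], p))[: len(members)]
        for strain, pool in zip(members, chosen):
            assignment[strain.strain_id] = pool
            loads[pool] += 1
    return assignment


def _gray_codes(n_bits: int) -> np.ndarray:
    """All 2^n binary-reflected Gray codes as an (2^n, n_bits) 0/1 array."""
    k = np.arange(1 << n_bits, dtype=np.uint32)
    gray = k ^ (k >> 1)
    bits = (gray[:, None] >> np.arange(n_bits - 1, -1, -1)) & 1
    return bits.astype(np.int8)


def design_signature_matrix(
    strain_ids: list[str], n_comb_pools: int, seed: int
) -> SignatureMatrix:
    """Give each strain a unique nonzero presence pattern over pools.

    Candidate patterns are the nonzero binary vectors enumerated in
    Gray-code order, shuffled with the seed, then stably sorted so that
    popcounts near ``n_comb_pools / 2`` come first — balanced patterns
    spread DNA mass evenly over the pools.  The first ``len(strain_ids)``
    patterns are taken, guaranteeing uniqueness without rejection
    sampling.

    Raises
    ------
    CapacityError
        If more strains than the 2^n - 1 available nonzero patterns.
    """
    if len(set(strain_ids)) != len(strain_ids):
        raise SchemaError("strain ids must be unique")
    n = len(strain_ids)
    capacity = (1 << n_comb_pools) - 1
    if n > capacity:
        raise CapacityError(
            f"{n} strains exceed the {capacity} distinct nonzero "
            f"signatures of {n_comb_pools} pools; add pools"
        )
    patterns = _gray_codes(n_comb_pools)
    patterns = patterns[patterns.any(axis=1)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patterns))
    patterns = patterns[perm]
    balance = np.abs(patterns.sum(axis=1) - n_comb_pools / 2.0)
    patterns = patterns[np.argsort(balance, kind="stable")]
    return SignatureMatrix(list(strain_ids), patterns[:n])


def validate_signature_matrix(
    m: SignatureMatrix, strains: list[StrainRecord]
) -> ValidationReport:
    """Check a design: duplicates per assembly pool, zero rows, min Hamming.

    Uniqueness is required only within each assembly pool because each
    pool's contigs are deconvolved against its own strains' signatures.
    """
    report = ValidationReport()
    known = {s.strain_id: s for s in strains}
    pool_of: dict[str, int] = {}
    for sid in m.strain_ids:
        if sid not in known:
            report.unknown_strains.append(sid)
        else:
            pool_of[sid] = known[sid].assembly_pool_id
    rows = {sid: m.row(sid) for sid in m.strain_ids if sid in known}
    for sid, row in rows.items():
        if not row.any():
            report.zero_rows.append(sid)
    sids = list(rows)
    hmin: int | None = None
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            d = int(np.sum(rows[a] != rows[b]))
            if pool_of[a] == pool_of[b]:
                if d == 0:
                    report.duplicate_rows.append((a, b))
                hmin = d if hmin is None else min(hmin, d)
    report.min_hamming = hmin
    return report
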