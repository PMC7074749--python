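"""Synthetic presence-absence communities with planted, recoverable structure.

The generator emulates the shape of spatially resolved T-RFLP data sets:
a few hundred fragments over 72 bulk or 104 single-particle samples grouped
into cores along a flow path. Three kinds of structure are planted on top of
i.i.d. background occupancy, each with full ground truth for recovery tests:

* **module blocks** — fragment blocks present with probability ``p_in`` in the
  samples of their associated cores and ``p_out`` elsewhere, producing the
  location-bound positive co-occurrence modules;
* **subset-dependency rules** — origin fragments whose sample set is built as
  a subset of their target's set, producing confidence-1 association rules
  (origins can be biased archaeal and targets bacterial to mirror the
  single-particle rule-type asymmetry);
* **exclusions** — fragment pairs with disjoint sample sets, producing
  significant negative correlations.

Cell-wise i.i.d. noise is applied after planting, and the surviving rules are
recomputed from the final matrix by a direct subset check, because a single
flipped cell is enough to break a confidence-1 rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import (
    ARCHAEAL,
    BACTERIAL,
    DOMAINS,
    FragmentAnnotation,
    PresenceAbsenceMatrix,
    SampleMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted block: ``size`` fragments tied to the samples of ``groups``."""

    size: int
    groups: tuple[str, ...]
    p_in: float = 0.9
    p_out: float = 0.05
    fraction_archaeal: float | None = None  # None -> config-level fraction


@dataclass(frozen=True)
class RuleSpec:
    """A planted subset dependency: samples(origin) built inside samples(target).

    ``origin`` and ``target`` are symbolic names; the generator creates one
    fragment per unique name, so several specs may share a target (one hub
    with many origins) or an origin.
    """

    origin: str
    target: str
    origin_domain: str = ARCHAEAL
    target_domain: str = BACTERIAL


@dataclass(frozen=True)
class SyntheticConfig:
    n_fragments: int
    sample_groups: tuple[tuple[str, int], ...]  # ordered (core label, n samples)
    scale: str = "bulk"
    fraction_archaeal: float = 0.3
    module_specs: tuple[ModuleSpec, ...] = ()
    rule_specs: tuple[RuleSpec, ...] = ()
    exclusion_specs: tuple[tuple[str, str], ...] = ()
    background_occupancy: float = 0.15
    rule_origin_occupancy: int = 6
    rule_target_extra: int = 12
    noise_rate: float = 0.02
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.sample_groups)

    def validate(self) -> None:
        probs = [self.fraction_archaeal, self.background_occupancy, self.noise_rate]
        for ms in self.module_specs:
            probs += [ms.p_in, ms.p_out]
            if ms.p_in <= ms.p_out:
                raise ValidationError(f"module spec requires p_in > p_out, got {ms}")
            unknown = set(ms.groups) - {g for g, _ in self.sample_groups}
            if unknown:
                raise ValidationError(f"module spec references unknown groups {unknown}")
        if any(p < 0 or p > 1 for p in probs if p is not None):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.rule_origin_occupancy < 1:
            raise ValidationError("rule origins need occupancy >= 1 (confidence undefined at 0)")
        names_o = {r.origin for r in self.rule_specs}
        names_t = {r.target for r in self.rule_specs}
        if names_o & names_t:
            raise ValidationError(f"names used both as origin and target: {names_o & names_t}")
        for r in self.rule_specs:
            if r.origin_domain not in DOMAINS or r.target_domain not in DOMAINS:
                raise ValidationError(f"bad domain in rule spec {r}")
        n_dedicated = (
            sum(ms.size for ms in self.module_specs)
            + len(names_o | names_t)
            + 2 * len(self.exclusion_specs)
        )
        if n_dedicated > self.n_fragments:
            raise ValidationError(
                f"planted structure needs {n_dedicated} fragments, config allows {self.n_fragments}"
            )
        if self.n_samples < 2:
            raise ValidationError("need at least two samples")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    module_membership: dict[str, int]
    planted_rules: tuple[tuple[str, str], ...]
    planted_exclusions: tuple[frozenset, ...]
    surviving_rules: tuple[tuple[str, str], ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "planted_rules": [list(r) for r in self.planted_rules],
            "planted_exclusions": [sorted(p) for p in self.planted_exclusions],
            "surviving_rules": [list(r) for r in self.surviving_rules],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_membership={k: int(v) for k, v in d["module_membership"].items()},
            planted_rules=tuple((a, b) for a, b in d["planted_rules"]),
            planted_exclusions=tuple(frozenset(p) for p in d["planted_exclusions"]),
            surviving_rules=tuple((a, b) for a, b in d["surviving_rules"]),
        )


@dataclass(frozen=True)
class SyntheticCommunity:
    matrix: PresenceAbsenceMatrix
    annotations: dict[str, FragmentAnnotation]
    metadata: dict[str, SampleMetadata]
    truth: SyntheticGroundTruth


def recompute_surviving_rules(
    m: PresenceAbsenceMatrix, planted: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Planted rules still exceptionless in the (possibly noisy) final matrix.

    A pair survives iff the origin occurs at least once and no sample has the
    origin present with the target absent.
    """
    out = []
    for origin, target in planted:
        ro, rt = m.row(origin), m.row(target)
        if ro.sum() >= 1 and not np.any(ro & ~rt.astype(bool)):
            out.append((origin, target))
    return out


def flip_noise(
    m: PresenceAbsenceMatrix, rate: float, seed: int | np.random.Generator
) -> PresenceAbsenceMatrix:
    """Flip every cell independently with probability ``rate``.

    At rate 1 this is the deterministic complement (applying it twice with
    any seeds restores the original matrix).
    """
    if not 0 <= rate <= 1:
        raise ValidationError("noise rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(m.values.shape) < rate
    return PresenceAbsenceMatrix(m.values ^ flips, m.fragment_ids, m.sample_ids)


def _make_metadata(config: SyntheticConfig) -> tuple[list[str], dict[str, SampleMetadata]]:
    sample_ids: list[str] = []
    metadata: dict[str, SampleMetadata] = {}
    for core, n in config.sample_groups:
        for k in range(n):
            if config.scale == "particle":
                section, particle = k // 8, k % 8 + 1
                sid = f"{core}_s{section + 1:02d}_p{particle}"
            else:
                section, particle = k, None
                sid = f"{core}_s{section + 1:02d}"
            sample_ids.append(sid)
            metadata[sid] = SampleMetadata(
                sample_id=sid,
                core=core,
                depth_section=section + 1,
                scale=config.scale,
                particle_index=particle,
            )
    return sample_ids, metadata


def generate(config: SyntheticConfig) -> SyntheticCommunity:
    """Draw a community matrix with planted structure and matching ground truth.

    Deterministic for a given config (all randomness flows from
    ``config.seed``); the returned truth's ``surviving_rules`` are recomputed
    from the final matrix after noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = config.n_samples
    sample_ids, metadata = _make_metadata(config)
    sample_core = np.array([metadata[s].core for s in sample_ids])

    rows: list[np.ndarray] = []
    domains: list[str] = []
    roles: list[str] = []  # parallel bookkeeping: module id / rule name / etc.
    membership_idx: dict[int, int] = {}

    for mod_id, ms in enumerate(config.module_specs, start=1):
        in_group = np.isin(sample_core, ms.groups)
        p = np.where(in_group, ms.p_in, ms.p_out)
        frac_arch = ms.fraction_archaeal if ms.fraction_archaeal is not None else config.fraction_archaeal
        for _ in range(ms.size):
            membership_idx[len(rows)] = mod_id
            rows.append((rng.random(S) < p).astype(np.int8))
            domains.append(ARCHAEAL if rng.random() < frac_arch else BACTERIAL)
            roles.append(f"module{mod_id}")

    # rule fragments: origins first (random small sets), then targets as supersets
    origin_names = sorted({r.origin for r in config.rule_specs})
    target_names = sorted({r.target for r in config.rule_specs})
    name_row: dict[str, int] = {}
    name_domain = {}
    for r in config.rule_specs:
        for name, dom in ((r.origin, r.origin_domain), (r.target, r.target_domain)):
            if name_domain.setdefault(name, dom) != dom:
                raise ValidationError(f"conflicting domains for rule fragment {name!r}")
    for name in origin_names:
        occ = min(config.rule_origin_occupancy, S)
        cells = np.zeros(S, dtype=np.int8)
        cells[rng.choice(S, size=occ, replace=False)] = 1
        name_row[name] = len(rows)
        rows.append(cells)
        domains.append(name_domain[name])
        roles.append(f"rule_origin:{name}")
    for name in target_names:
        base = np.zeros(S, dtype=np.int8)
        for r in config.rule_specs:
            if r.target == name:
                base |= rows[name_row[r.origin]]
        extra_pool = np.flatnonzero(base == 0)
        n_extra = min(config.rule_target_extra, extra_pool.size)
        if n_extra:
            base = base.copy()
            base[rng.choice(extra_pool, size=n_extra, replace=False)] = 1
        name_row[name] = len(rows)
        rows.append(base)
        domains.append(name_domain[name])
        roles.append(f"rule_target:{name}")

    exclusion_rows: list[tuple[int, int]] = []
    for a_name, b_name in config.exclusion_specs:
        half = rng.permutation(S)
        cells_a = np.zeros(S, dtype=np.int8)
        cells_b = np.zeros(S, dtype=np.int8)
        cells_a[half[: S // 2]] = 1
        cells_b[half[S // 2 :]] = 1
        exclusion_rows.append((len(rows), len(rows) + 1))
        for cells, nm in ((cells_a, a_name), (cells_b, b_name)):
            rows.append(cells)
            domains.append(ARCHAEAL if rng.random() < config.fraction_archaeal else BACTERIAL)
            roles.append(f"exclusion:{nm}")

    n_background = config.n_fragments - len(rows)
    for _ in range(n_background):
        rows.append((rng.random(S) < config.background_occupancy).astype(np.int8))
        domains.append(ARCHAEAL if rng.random() < config.fraction_archaeal else BACTERIAL)
        roles.append("background")

    # paper-style ids: separate counters per domain
    counters = {BACTERIAL: 0, ARCHAEAL: 0}
    fragment_ids = []
    for dom in domains:
        counters[dom] += 1
        prefix = "Bact" if dom == BACTERIAL else "Arch"
        fragment_ids.append(f"{prefix}_{counters[dom]:03d}")

    clean = PresenceAbsenceMatrix(np.vstack(rows), fragment_ids, sample_ids)
    matrix = flip_noise(clean, config.noise_rate, rng) if config.noise_rate > 0 else clean

    annotations = {
        fid: FragmentAnnotation(fragment_id=fid, domain=dom)
        for fid, dom in zip(fragment_ids, domains)
    }
    planted_rules = tuple(
        (fragment_ids[name_row[r.origin]], fragment_ids[name_row[r.target]])
        for r in config.rule_specs
    )
    truth = SyntheticGroundTruth(
        module_membership={
            fragment_ids[i]: mod for i, mod in membership_idx.items()
        },
        planted_rules=planted_rules,
        planted_exclusions=tuple(
            frozenset((fragment_ids[i], fragment_ids[j])) for i, j in exclusion_rows
        ),
        surviving_rules=tuple(recompute_surviving_rules(matrix, planted_rules)),
    )
    return SyntheticCommunity(matrix=matrix, annotations=annotations, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# presets mirroring the two study scales


def bulk_like(seed: int = 0, noise_rate: float = 0.02) -> SyntheticConfig:
    """Bulk-sample preset: 280 fragments x 72 samples, five localized modules.

    Five 12-fragment modules are tied to one core each (mirroring the five
    location-bound modules of the bulk network), 20 rules with mixed domains
    are planted through 10 shared targets, and 6 exclusion pairs span
    complementary sample halves.
    """
    rule_specs = []
    for t in range(10):
        t_dom = BACTERIAL if t % 2 == 0 else ARCHAEAL
        for o in range(2):
            o_dom = ARCHAEAL if (t + o) % 2 == 0 else BACTERIAL
            rule_specs.append(
                RuleSpec(
                    origin=f"O{t:02d}_{o}",
                    target=f"T{t:02d}",
                    origin_domain=o_dom,
                    target_domain=t_dom,
                )
            )
    return SyntheticConfig(
        n_fragments=280,
        sample_groups=(("C1", 15), ("C2", 15), ("C3", 15), ("C5", 15), ("C8", 12)),
        scale="bulk",
        fraction_archaeal=0.27,
        module_specs=tuple(
            ModuleSpec(size=12, groups=(core,), p_in=0.9, p_out=0.05)
            for core in ("C1", "C2", "C3", "C5", "C8")
        ),
        rule_specs=tuple(rule_specs),
        exclusion_specs=tuple((f"X{i}a", f"X{i}b") for i in range(6)),
        background_occupancy=0.15,
        rule_origin_occupancy=6,
        rule_target_extra=12,
        noise_rate=noise_rate,
        seed=seed,
    )


def particle_like(seed: int = 0, noise_rate: float = 0.02) -> SyntheticConfig:
    """Single-particle preset: 620 fragments x 104 samples, archaeal rule origins.

    104 samples are 13 four-centimetre sections x 8 particles across the five
    cores. Fifty sparse archaeal origins each feed three of thirty bacterial
    targets (150 planted rules), reproducing the archaeum -> bacterium rule
    dominance and the bacterial target-only hubs; module structure is weaker
    than in the bulk preset (three 10-fragment blocks).
    """
    rule_specs = tuple(
        RuleSpec(
            origin=f"O{i:02d}",
            target=f"T{(3 * i + k) % 30:02d}",
            origin_domain=ARCHAEAL,
            target_domain=BACTERIAL,
        )
        for i in range(50)
        for k in range(3)
    )
    return SyntheticConfig(
        n_fragments=620,
        sample_groups=(("C1", 16), ("C2", 16), ("C3", 24), ("C5", 32), ("C8", 16)),
        scale="particle",
        fraction_archaeal=0.48,
        module_specs=tuple(
            ModuleSpec(size=10, groups=(core,), p_in=0.85, p_out=0.05)
            for core in ("C2", "C3", "C5")
        ),
        rule_specs=rule_specs,
        exclusion_specs=tuple((f"X{i}a", f"X{i}b") for i in range(8)),
        background_occupancy=0.15,
        rule_origin_occupancy=5,
        rule_target_extra=10,
        noise_rate=noise_rate,
        seed=seed,
    )
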