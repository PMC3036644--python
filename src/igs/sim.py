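"""Forward simulation of IGS evolution along a species tree.

The simulator evolves a structured intergenic spacer — nonrepetitive N1,
an interleaved repeat array (types A/B/C...), nonrepetitive N2 — down a
newick species tree whose branch lengths are expected substitutions per
site.  Within each branch a Gillespie event sequence draws:

* JC69 point mutations (rate per site per unit time);
* gene conversions: a geometric-length tract copied from one repeat
  copy onto another copy of the same type within the array;
* unequal crossovers: duplication or deletion of a single repeat unit
  (copy number never drops below one per type);
* indels in the nonrepetitive regions (geometric lengths);
* scheduled hybridization events replacing a region of one lineage with
  the homologous region of another lineage at a stated time.

When ``terminal_repeat_protected`` is set, the first and last units of
the array take part in neither conversion nor crossover, mirroring the
observation that terminal repeats tend to escape homogenization.

Every event is logged with all of its sampled choices, so replaying the
log from the ancestral template reproduces the emitted sequences
byte-for-byte; the log also records per-leaf repeat annotations and,
for each unit, the template unit it descends from (its ``origin``),
which gives tests an orthology oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .records import IGSRecord
from .repeats import RepeatAnnotation, RepeatUnit

__all__ = [
    "SimConfig",
    "SimTruth",
    "Hybridization",
    "simulate_igs",
    "replay",
    "regime_fixture",
    "study_cohort_config",
    "write_truth",
    "read_truth",
    "repeat_records",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Hybridization:
    donor: str  # leaf name identifying the donor lineage
    recipient: str
    time: float  # distance from the root, same units as branch lengths
    region: str  # "N1" | "R" | "N2"
    interval: tuple[int, int] | None = None  # optional sub-interval (region coords)


@dataclass
class SimConfig:
    """Study conditions for one simulated IGS cohort.

    Branch lengths (and hence event times) are in expected
    substitutions per site, so `mutation_rate` is 1.0 by construction
    and the other rates are scaled per that clock.
    """

    tree: str  # newick with branch lengths
    n1_len: int = 700
    n2_len: int = 2700
    unit_lengths: dict = field(default_factory=lambda: {"A": 200, "B": 130, "C": 90})
    array: str = "ABABCC"
    paralog_divergence: float = 0.06  # per-copy divergence from the type consensus in the template
    mutation_rate: float = 1.0
    conversion_rate: float = 0.0  # per ordered eligible same-type unit pair per unit time
    conversion_tract_mean: float = 100.0
    crossover_rate: float = 0.0  # per eligible unit per unit time
    terminal_repeat_protected: bool = True
    indel_rate: float = 0.0  # per N1/N2 site per unit time
    indel_mean_len: float = 20.0
    hybridizations: tuple = ()
    species_map: dict | None = None  # leaf -> species; default: strip trailing digits/letters
    seed: int = 0

    def __post_init__(self):
        for r in (self.mutation_rate, self.conversion_rate,
                  self.crossover_rate, self.indel_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.conversion_tract_mean < 1:
            raise ValueError("conversion tract mean must be >= 1")
        if not set(self.array) <= set(self.unit_lengths):
            raise ValueError("array uses types without a unit length")

    def species_of(self, leaf: str) -> str:
        if self.species_map and leaf in self.species_map:
            return self.species_map[leaf]
        return leaf.rstrip("0123456789ab")

    def individual_of(self, leaf: str) -> str:
        # two clones from one individual are suffixed a/b (DpxE1a, DpxE1b)
        return leaf[:-1] if leaf and leaf[-1] in "ab" else leaf


@dataclass
class SimTruth:
    template: dict  # {"n1": str, "units": [{"uid","type","seq"}], "n2": str}
    events: list  # chronological event dicts
    leaf_annotations: dict  # leaf -> [{"uid","origin","type","start","end"}]
    leaf_names: list


# ---------------------------------------------------------------------------
# tree handling (plain newick, leaf names + branch lengths)


@dataclass
class _Node:
    name: str | None
    length: float
    children: list


def _parse_newick(text: str) -> _Node:
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            if text[pos] != ")":
                raise ValueError("unbalanced newick")
            pos += 1
            name, length = _label()
            return _Node(name=name or None, length=length, children=children)
        name, length = _label()
        if not name:
            raise ValueError("leaf without a name in newick")
        return _Node(name=name, length=length, children=[])

    def _label():
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        name = text[start:pos]
        length = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            length = float(text[start:pos])
        return name, length

    node = parse()
    if pos != len(text):
        raise ValueError("trailing characters in newick")
    return node


@dataclass
class _Branch:
    id: int
    parent: int | None
    t_start: float
    t_end: float
    children: list
    leaf_name: str | None
    leaves: frozenset


def _branch_schedule(tree: _Node) -> list[_Branch]:
    branches: list[_Branch] = []

    def walk(node: _Node, parent: int | None, t0: float) -> _Branch:
        bid = len(branches)
        b = _Branch(id=bid, parent=parent, t_start=t0, t_end=t0 + node.length,
                    children=[], leaf_name=None, leaves=frozenset())
        branches.append(b)
        if node.children:
            leaves = set()
            for c in node.children:
                cb = walk(c, bid, b.t_end)
                b.children.append(cb.id)
                leaves |= cb.leaves
            b.leaves = frozenset(leaves)
        else:
            b.leaf_name = node.name
            b.leaves = frozenset([node.name])
        return b

    walk(tree, None, 0.0)
    return branches


# ---------------------------------------------------------------------------
# lineage state and event application


class _State:
    __slots__ = ("n1", "units", "n2")

    def __init__(self, n1, units, n2):
        self.n1 = n1  # np.uint8 codes 0..3
        self.units = units  # list of [uid, origin, type, np.array]
        self.n2 = n2

    def clone(self) -> "_State":
        return _State(self.n1.copy(),
                      [[u, o, t, s.copy()] for u, o, t, s in self.units],
                      self.n2.copy())

    @property
    def total_len(self) -> int:
        return len(self.n1) + sum(len(s) for _, _, _, s in self.units) + len(self.n2)

    def sequence(self) -> str:
        parts = [self.n1] + [s for _, _, _, s in self.units] + [self.n2]
        return "".join(_BASES[b] for b in np.concatenate(parts))

    def annotation(self) -> list[dict]:
        out = []
        pos = len(self.n1)
        for uid, origin, t, s in self.units:
            out.append({"uid": uid, "origin": origin, "type": t,
                        "start": pos, "end": pos + len(s)})
            pos += len(s)
        return out


def _apply_event(states: dict, ev: dict) -> None:
    """Apply one logged event to the lineage states (shared by the
    simulator and the replay oracle)."""
    st: _State = states[ev["branch"]]
    kind = ev["type"]
    if kind == "mutation":
        region = ev["region"]
        if region == "n1":
            st.n1[ev["pos"]] = ev["to"]
        elif region == "n2":
            st.n2[ev["pos"]] = ev["to"]
        else:
            st.units[ev["unit_index"]][3][ev["pos"]] = ev["to"]
    elif kind == "conversion":
        d, r = ev["donor_index"], ev["recipient_index"]
        s, l = ev["start"], ev["length"]
        st.units[r][3][s:s + l] = st.units[d][3][s:s + l].copy()
    elif kind == "crossover_dup":
        i = ev["unit_index"]
        uid, origin, t, s = st.units[i]
        st.units.insert(i + 1, [ev["new_uid"], origin, t, s.copy()])
    elif kind == "crossover_del":
        del st.units[ev["unit_index"]]
    elif kind == "insertion":
        arr = st.n1 if ev["region"] == "n1" else st.n2
        ins = np.array([_BASES.index(c) for c in ev["seq"]], dtype=np.uint8)
        new = np.concatenate([arr[:ev["pos"]], ins, arr[ev["pos"]:]])
        setattr(st, ev["region"], new)
    elif kind == "deletion":
        arr = st.n1 if ev["region"] == "n1" else st.n2
        new = np.concatenate([arr[:ev["pos"]], arr[ev["pos"] + ev["length"]:]])
        setattr(st, ev["region"], new)
    elif kind == "hybridization":
        donor = states[ev["donor_branch"]]
        region = ev["region"]
        if region == "R":
            st.units = [[u, o, t, s.copy()] for u, o, t, s in donor.units]
        else:
            attr = region.lower()
            src = getattr(donor, attr)
            if ev.get("interval") is not None:
                lo, hi = ev["interval"]
                dst = getattr(st, attr)
                hi = min(hi, len(src), len(dst))
                dst[lo:hi] = src[lo:hi].copy()
            else:
                setattr(st, attr, src.copy())
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown event type {kind!r}")


# ---------------------------------------------------------------------------
# the simulator proper


def _make_template(cfg: SimConfig, rng) -> _State:
    def rand_seq(n):
        return rng.integers(0, 4, size=n).astype(np.uint8)

    def mutate(seq, p):
        s = seq.copy()
        hit = rng.random(len(s)) < p
        s[hit] = (s[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return s

    n1 = rand_seq(cfg.n1_len)
    n2 = rand_seq(cfg.n2_len)
    consensus = {t: rand_seq(l) for t, l in cfg.unit_lengths.items()}
    units = []
    for k, t in enumerate(cfg.array):
        units.append([k, k, t, mutate(consensus[t], cfg.paralog_divergence)])
    return _State(n1, units, n2)


def _eligible_unit_indices(st: _State, protected: bool) -> list[int]:
    n = len(st.units)
    if protected and n > 2:
        return list(range(1, n - 1))
    if protected and n <= 2:
        return []
    return list(range(n))


def _conversion_pairs(st: _State, protected: bool) -> list[tuple[int, int]]:
    idx = _eligible_unit_indices(st, protected)
    out = []
    for i in idx:
        for j in idx:
            if i != j and st.units[i][2] == st.units[j][2]:
                out.append((i, j))
    return out


def _deletable(st: _State, i: int) -> bool:
    t = st.units[i][2]
    return sum(1 for u in st.units if u[2] == t) > 1


def _gillespie_branch(cfg: SimConfig, rng, st: _State, branch_id: int,
                      t0: float, t1: float, events: list, uid_counter: list):
    t = t0
    while True:
        L = st.total_len
        nr_len = len(st.n1) + len(st.n2)
        pairs = _conversion_pairs(st, cfg.terminal_repeat_protected)
        xunits = _eligible_unit_indices(st, cfg.terminal_repeat_protected)
        r_mut = cfg.mutation_rate * L
        r_conv = cfg.conversion_rate * len(pairs)
        r_xo = cfg.crossover_rate * len(xunits)
        r_ind = cfg.indel_rate * nr_len
        total = r_mut + r_conv + r_xo + r_ind
        if total <= 0:
            return
        t = t + rng.exponential(1.0 / total)
        if t >= t1:
            return
        u = rng.random() * total
        if u < r_mut:
            site = int(rng.integers(0, L))
            ev = {"type": "mutation", "time": t, "branch": branch_id}
            if site < len(st.n1):
                ev.update(region="n1", pos=site, frm=int(st.n1[site]))
            else:
                site -= len(st.n1)
                placed = False
                for k, (_, _, _, s) in enumerate(st.units):
                    if site < len(s):
                        ev.update(region="unit", unit_index=k,
                                  uid=st.units[k][0], pos=site, frm=int(s[site]))
                        placed = True
                        break
                    site -= len(s)
                if not placed:
                    ev.update(region="n2", pos=site, frm=int(st.n2[site]))
            ev["to"] = int((ev["frm"] + rng.integers(1, 4)) % 4)
        elif u < r_mut + r_conv:
            d, r = pairs[int(rng.integers(0, len(pairs)))]
            ulen = len(st.units[r][3])
            start = int(rng.integers(0, ulen))
            length = int(min(rng.geometric(1.0 / cfg.conversion_tract_mean),
                             ulen - start))
            ev = {"type": "conversion", "time": t, "branch": branch_id,
                  "donor_index": d, "recipient_index": r,
                  "donor_uid": st.units[d][0], "recipient_uid": st.units[r][0],
                  "start": start, "length": length}
        elif u < r_mut + r_conv + r_xo:
            i = xunits[int(rng.integers(0, len(xunits)))]
            dup = bool(rng.random() < 0.5) or not _deletable(st, i)
            if dup:
                uid_counter[0] += 1
                ev = {"type": "crossover_dup", "time": t, "branch": branch_id,
                      "unit_index": i, "source_uid": st.units[i][0],
                      "new_uid": uid_counter[0]}
            else:
                ev = {"type": "crossover_del", "time": t, "branch": branch_id,
                      "unit_index": i, "uid": st.units[i][0]}
        else:
            region = "n1" if rng.random() * nr_len < len(st.n1) else "n2"
            arr = st.n1 if region == "n1" else st.n2
            length = int(rng.geometric(1.0 / cfg.indel_mean_len))
            if rng.random() < 0.5:
                pos = int(rng.integers(0, len(arr) + 1))
                seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
                ev = {"type": "insertion", "time": t, "branch": branch_id,
                      "region": region, "pos": pos, "seq": seq}
            else:
                if len(arr) <= length:
                    continue  # refuse to delete a whole region
                pos = int(rng.integers(0, len(arr) - length))
                ev = {"type": "deletion", "time": t, "branch": branch_id,
                      "region": region, "pos": pos, "length": length}
        events.append(ev)
        _apply_event({branch_id: st}, ev)


def _run(cfg: SimConfig, logged_events: list | None = None):
    """Shared scheduler: chronological branch advance with hybridization
    checkpoints.  Samples events when `logged_events` is None, otherwise
    replays them."""
    rng = np.random.default_rng(cfg.seed)
    tree = _parse_newick(cfg.tree)
    branches = _branch_schedule(tree)
    leaves = [b for b in branches if b.leaf_name]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    t_max = max(b.t_end for b in branches)

    template = _make_template(cfg, rng)
    uid_counter = [max(u[0] for u in template.units)]

    hybs = sorted(cfg.hybridizations, key=lambda h: h.time)
    for h in hybs:
        if not (0 < h.time < t_max):
            raise ValueError("hybridization time outside the tree depth")
    checkpoints = [0.0] + sorted({h.time for h in hybs}) + [t_max + 1e-12]

    states: dict[int, _State] = {0: template.clone()}
    done_to: dict[int, float] = {0: branches[0].t_start}
    events: list[dict] = []
    replay_buf: list[dict] = list(logged_events) if logged_events is not None else []

    def advance(bid: int, upto: float):
        b = branches[bid]
        lo = done_to[bid]
        hi = min(upto, b.t_end)
        st = states[bid]
        if hi > lo:
            if logged_events is None:
                _gillespie_branch(cfg, rng, st, bid, lo, hi, events, uid_counter)
            else:
                for ev in replay_buf:
                    if ev["branch"] == bid and lo <= ev["time"] < hi \
                            and ev["type"] != "hybridization":
                        _apply_event(states, ev)
            done_to[bid] = hi
        if done_to[bid] >= b.t_end:
            for cid in b.children:
                if cid not in states:
                    states[cid] = st.clone()
                    done_to[cid] = branches[cid].t_start

    order = sorted(range(len(branches)), key=lambda i: (branches[i].t_start, i))
    for T0, T1 in zip(checkpoints[:-1], checkpoints[1:]):
        # parents precede children in `order`, so a child created when
        # its parent completes is advanced later in this same sweep
        for bid in order:
            if bid in states:
                advance(bid, T1)
        # hybridizations scheduled exactly at T1
        for h in hybs:
            if h.time != T1:
                continue
            db = _lineage_at(branches, h.donor, h.time)
            rb = _lineage_at(branches, h.recipient, h.time)
            ev = {"type": "hybridization", "time": h.time, "branch": rb,
                  "donor_branch": db, "region": h.region,
                  "interval": list(h.interval) if h.interval else None}
            events.append(ev)
            _apply_event(states, ev)

    records = []
    annotations = {}
    for b in sorted(leaves, key=lambda b: b.leaf_name):
        st = states[b.id]
        records.append(IGSRecord(
            id=b.leaf_name, species=cfg.species_of(b.leaf_name),
            individual=cfg.individual_of(b.leaf_name), sequence=st.sequence(),
        ))
        annotations[b.leaf_name] = st.annotation()
    truth = SimTruth(
        template={
            "n1": "".join(_BASES[x] for x in template.n1),
            "units": [{"uid": u, "origin": o, "type": t,
                       "seq": "".join(_BASES[x] for x in s)}
                      for u, o, t, s in template.units],
            "n2": "".join(_BASES[x] for x in template.n2),
        },
        events=events if logged_events is None else list(logged_events),
        leaf_annotations=annotations,
        leaf_names=[b.leaf_name for b in sorted(leaves, key=lambda b: b.leaf_name)],
    )
    return records, truth


def _lineage_at(branches: list[_Branch], leaf: str, time: float) -> int:
    for b in branches:
        if leaf in b.leaves and b.t_start <= time < b.t_end:
            return b.id
    raise ValueError(f"no lineage containing {leaf!r} is active at time {time}")


def simulate_igs(config: SimConfig) -> tuple[list[IGSRecord], SimTruth]:
    """Simulate one IGS per leaf of the species tree; returns records
    sorted by leaf name plus the truth log."""
    return _run(config)


def replay(config: SimConfig, truth: SimTruth) -> list[IGSRecord]:
    """Re-derive the leaf sequences by applying the logged events to the
    ancestral template (the determinism/exactness oracle)."""
    records, _ = _run(config, logged_events=truth.events)
    return records


# ---------------------------------------------------------------------------
# truth serialization (1-based inclusive coordinates on disk)


_POS_KEYS = ("pos", "start")


def write_truth(truth: SimTruth, path) -> None:
    obj = {
        "template": truth.template,
        "leaf_names": truth.leaf_names,
        "events": [],
        "leaf_annotations": {},
    }
    for ev in truth.events:
        e = dict(ev)
        for k in _POS_KEYS:
            if k in e:
                e[k] = e[k] + 1
        if e.get("interval"):
            e["interval"] = [e["interval"][0] + 1, e["interval"][1]]
        obj["events"].append(e)
    for leaf, ann in truth.leaf_annotations.items():
        obj["leaf_annotations"][leaf] = [
            {**u, "start": u["start"] + 1, "end": u["end"]} for u in ann
        ]
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        obj = json.load(fh)
    events = []
    for e in obj["events"]:
        e = dict(e)
        for k in _POS_KEYS:
            if k in e:
                e[k] = e[k] - 1
        if e.get("interval"):
            e["interval"] = [e["interval"][0] - 1, e["interval"][1]]
        events.append(e)
    ann = {
        leaf: [{**u, "start": u["start"] - 1, "end": u["end"]} for u in units]
        for leaf, units in obj["leaf_annotations"].items()
    }
    return SimTruth(template=obj["template"], events=events,
                    leaf_annotations=ann, leaf_names=obj["leaf_names"])


def truth_annotation(truth: SimTruth, leaf: str) -> RepeatAnnotation:
    """The true RepeatAnnotation for one emitted leaf."""
    counts: dict[str, int] = {}
    units = []
    for u in truth.leaf_annotations[leaf]:
        counts[u["type"]] = counts.get(u["type"], 0) + 1
        units.append(RepeatUnit(type_label=u["type"],
                                interval=(u["start"], u["end"]),
                                copy_index=counts[u["type"]]))
    return RepeatAnnotation(record_id=leaf, units=tuple(units))


# ---------------------------------------------------------------------------
# the synthetic study cohort: 13 IGS sequences from 10 individuals of
# 4 species, mirroring the sampling design of the real study (3 DpxNA,
# 3 Dpc, 1 Dten, and 2 clones from each of 3 DpxE individuals), with
# species splits scaled so condensed-IGS divergences land in the
# observed 0.01-0.04 range


_NA = "((DpxNA1:0.003,DpxNA2:0.003):0.002,DpxNA3:0.005)"
_DP = "((Dpc1:0.003,Dpc2:0.003):0.002,Dpc3:0.005)"
_E12 = "((DpxE1a:0.001,DpxE1b:0.001):0.004,(DpxE2a:0.001,DpxE2b:0.001):0.004)"
_E = f"({_E12}:0.003,(DpxE3a:0.001,DpxE3b:0.001):0.007)"
_STUDY_TREE = (
    f"((({_NA}:0.005,{_DP}:0.005):0.005,Dten:0.015):0.005,{_E}:0.012);"
)


def study_cohort_config(seed: int = 0) -> SimConfig:
    """Conditions for the synthetic stand-in of the 13-sequence study.

    Conversion is rare (the position-specific regime the study
    observed), unequal crossover generates copy-number variation with
    terminal repeats protected, and indels occur in the nonrepetitive
    regions.  Two of the three DpxE individuals carry introgressed IGS
    copies — the whole spacer replaced from the Dten and Dpc lineages
    shortly before sampling — reproducing the hybrid individuals whose
    inadvertent inclusion shaped the study's divergence patterns.
    Template sizes are desk-scaled (see the methods note).
    """
    intro = []
    for region in ("N1", "R", "N2"):
        intro.append(Hybridization(donor="Dten", recipient="DpxE1a",
                                   time=0.018, region=region))
        intro.append(Hybridization(donor="Dpc1", recipient="DpxE2a",
                                   time=0.018, region=region))
    # partial N2 tracts: interchromosomal gene conversion in hybrids,
    # the mosaic signal the conversion screen is meant to recover
    intro.append(Hybridization(donor="Dten", recipient="Dpc2",
                               time=0.019, region="N2", interval=(300, 700)))
    intro.append(Hybridization(donor="DpxNA1", recipient="Dpc3",
                               time=0.019, region="N2", interval=(750, 1150)))
    return SimConfig(
        tree=_STUDY_TREE,
        n1_len=400, n2_len=1200,
        unit_lengths={"A": 200, "B": 130, "C": 90},
        array="ABABCC",
        paralog_divergence=0.06,
        conversion_rate=1.0,
        crossover_rate=40.0,
        terminal_repeat_protected=True,
        indel_rate=0.01,
        indel_mean_len=25.0,
        hybridizations=tuple(intro),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# regime fixtures


_EIGHT_LEAF_TREE = (
    "((((DpxNA1:0.004,DpxNA2:0.004):0.006,(Dpc1:0.004,Dpc2:0.004):0.006):0.005,"
    "(Dten1:0.004,Dten2:0.004):0.011):0.005,(DpxE1:0.004,DpxE2:0.004):0.016);"
)

_SPECIES_MAP = {
    "DpxNA1": "DpxNA", "DpxNA2": "DpxNA", "Dpc1": "Dpc", "Dpc2": "Dpc",
    "Dten1": "Dten", "Dten2": "Dten", "DpxE1": "DpxE", "DpxE2": "DpxE",
}

# desk-scale template used by the regime bundles (documented in the
# methods note); N2 is kept long enough to carry a usable number of
# polymorphic sites, as in the real spacer where N2 is ~2.5 kb.
# The full-size defaults remain on SimConfig itself.
_FIXTURE_SIZES = dict(n1_len=250, n2_len=1200,
                      unit_lengths={"A": 150, "B": 100, "C": 80})


def regime_fixture(regime: str, seed: int = 0):
    """Named simulation bundles for the three headline regimes.

    position_specific: conversion rare -> orthologous (same array
    position) repeats stay more similar than paralogs.
    concerted: conversion frequent (and unconstrained by terminal
    protection) -> within-array homogenization.
    hybrid: two lineages exchange the N2 region late in the tree.
    """
    common = dict(tree=_EIGHT_LEAF_TREE, species_map=_SPECIES_MAP,
                  array="ABABCC", paralog_divergence=0.06, seed=seed,
                  **_FIXTURE_SIZES)
    if regime == "position_specific":
        cfg = SimConfig(conversion_rate=1.0, crossover_rate=2.0,
                        terminal_repeat_protected=True, **common)
    elif regime == "concerted":
        cfg = SimConfig(conversion_rate=400.0, crossover_rate=2.0,
                        terminal_repeat_protected=False, **common)
    elif regime == "hybrid":
        # recent introgression: the sampled individual carries a nearly
        # intact allospecific N2, as in hybrids caught within a few
        # generations of the cross
        cfg = SimConfig(conversion_rate=1.0, crossover_rate=0.0,
                        hybridizations=(
                            Hybridization(donor="Dten1", recipient="DpxE1",
                                          time=0.0195, region="N2"),
                        ),
                        **common)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    records, truth = simulate_igs(cfg)
    return {"regime": regime, "config": cfg, "records": records, "truth": truth}


# ---------------------------------------------------------------------------
# repeat-level helpers for regime scoring


def repeat_records(records: list[IGSRecord], truth: SimTruth,
                   type_label: str | None = None):
    """Flatten leaf repeat copies: (leaf, origin, type, position, seq)."""
    out = []
    by_id = {r.id: r for r in records}
    for leaf in truth.leaf_names:
        pos_by_type: dict[str, int] = {}
        for u in truth.leaf_annotations[leaf]:
            t = u["type"]
            pos_by_type[t] = pos_by_type.get(t, 0) + 1
            if type_label and t != type_label:
                continue
            seq = by_id[leaf].sequence[u["start"]:u["end"]]
            out.append({"leaf": leaf, "origin": u["origin"], "type": t,
                        "position": pos_by_type[t], "seq": seq})
    return out


def _hamming_p(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return float("nan")
    d = sum(1 for x, y in zip(a[:n], b[:n]) if x != y)
    return d / n


def position_clustering_score(records, truth, species_of) -> tuple[float, float]:
    """(within-origin mean, between-origin mean) p-distance over
    same-type repeat pairs from different arrays."""
    reps = repeat_records(records, truth)
    within, between = [], []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i], reps[j]
            if a["type"] != b["type"] or a["leaf"] == b["leaf"]:
                continue
            d = _hamming_p(a["seq"], b["seq"])
            (within if a["origin"] == b["origin"] else between).append(d)
    w = float(np.mean(within)) if within else float("nan")
    x = float(np.mean(between)) if between else float("nan")
    return w, x


def concerted_score(records, truth, species_of) -> tuple[float, float]:
    """(within-array mean, between-species mean) p-distance over
    same-type repeat pairs."""
    reps = repeat_records(records, truth)
    within_array, between_species = [], []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i], reps[j]
            if a["type"] != b["type"]:
                continue
            d = _hamming_p(a["seq"], b["seq"])
            if a["leaf"] == b["leaf"]:
                within_array.append(d)
            elif species_of(a["leaf"]) != species_of(b["leaf"]):
                between_species.append(d)
    w = float(np.mean(within_array)) if within_array else float("nan")
    x = float(np.mean(between_species)) if between_species else float("nan")
    return w, x
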