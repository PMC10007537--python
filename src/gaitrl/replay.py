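"""Segment-based prioritized experience replay.

Episodes are cut into fixed-length segments that overlap by half their
length and never cross episode boundaries. Each segment carries a scalar
priority computed from its n-step TD-error magnitudes,

    p = eta * max_i(delta_i) + (1 - eta) * mean_i(delta_i),  eta = 0.9,

segments are sampled with probability proportional to p^alpha, and sampled
elements carry importance weights (N * P)^(-beta) normalized by their
maximum. Both exponents are annealed linearly from 0.1 to 0.9 over the
first 3000 training steps. Eviction is first-in-first-out at a fixed
transition capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError
from .rewards import N_COMPONENTS


@dataclass
class Transition:
    """One environment step: (s, a, r-vector, s', done) plus bookkeeping."""

    observation: np.ndarray
    action: np.ndarray
    reward: np.ndarray  # reward vector, length N_COMPONENTS
    next_observation: np.ndarray
    done: bool
    episode_id: int
    t: int  # timestep index within the episode

    def __post_init__(self):
        self.observation = np.asarray(self.observation, dtype=np.float64)
        self.action = np.asarray(self.action, dtype=np.float64)
        self.reward = np.asarray(self.reward, dtype=np.float64)
        self.next_observation = np.asarray(self.next_observation, dtype=np.float64)
        if self.reward.shape != (N_COMPONENTS,):
            raise ContractError(
                f"reward vector must have {N_COMPONENTS} components, "
                f"got {self.reward.shape}"
            )


@dataclass
class Segment:
    """Fixed-length slice of consecutive same-episode transitions.

    ``mask`` flags real (non-padded) positions; short episode tails are
    right-padded by repeating the final transition, and padded positions are
    excluded from loss computations via the mask.
    """

    transitions: list[Transition]
    mask: np.ndarray
    priority: float = 0.0
    insertion: int = -1  # monotone counter assigned by the store

    def __post_init__(self):
        eids = {tr.episode_id for tr in self.transitions}
        if len(eids) != 1:
            raise ContractError("segment spans multiple episodes")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.transitions),):
            raise ContractError("mask length != segment length")
        if not (np.isfinite(self.priority) and self.priority >= 0):
            raise ContractError("priority must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def episode_id(self) -> int:
        return self.transitions[0].episode_id

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class PrioritySchedule:
    """Linear ramp of the priority exponents alpha and beta.

    Both start at 0.1 and increase linearly to 0.9 over the first 3000
    training steps, then stay clamped at 0.9.
    """

    start: float = 0.1
    end: float = 0.9
    ramp_steps: int = 3000

    def exponents(self, step: int) -> tuple[float, float]:
        if step < 0:
            raise ConfigError("training step must be >= 0")
        if self.ramp_steps <= 0:
            return self.end, self.end
        frac = min(1.0, step / self.ramp_steps)
        val = self.start + frac * (self.end - self.start)
        return val, val


def segmentize(episode: Sequence[Transition], L: int) -> list[Segment]:
    """Cut one episode into half-overlapping segments of length ``L``.

    Segments start at offsets 0, L/2, L, ... A tail shorter than L is
    right-padded with the final transition and masked. Offsets at or past
    the episode end produce nothing, and every transition is covered.
    """
    if L < 2 or L % 2 != 0:
        raise ConfigError(f"segment length must be even and >= 2, got {L}")
    if len(episode) == 0:
        raise ContractError("empty episode")
    eid = episode[0].episode_id
    if any(tr.episode_id != eid for tr in episode):
        raise ContractError("segmentize expects a single episode")
    n = len(episode)
    segments: list[Segment] = []
    offset = 0
    while offset < n:
        chunk = list(episode[offset : offset + L])
        n_real = len(chunk)
        if n_real < L:
            chunk = chunk + [chunk[-1]] * (L - n_real)
        mask = np.zeros(L, dtype=bool)
        mask[:n_real] = True
        segments.append(Segment(transitions=chunk, mask=mask))
        if offset + L >= n:
            break
        offset += L // 2
    return segments


def priority(deltas: Sequence[float], eta: float = 0.9) -> float:
    """Segment priority from n-step TD-error magnitudes:
    ``eta * max(deltas) + (1 - eta) * mean(deltas)``."""
    deltas = np.asarray(deltas, dtype=np.float64)
    if deltas.size == 0:
        raise ContractError("priority needs at least one TD error")
    if np.any(deltas < 0):
        raise ContractError("TD-error magnitudes must be non-negative")
    if not 0.0 <= eta <= 1.0:
        raise ConfigError(f"eta must be in [0, 1], got {eta}")
    return float(eta * deltas.max() + (1.0 - eta) * deltas.mean())


class SegmentReplay:
    """FIFO-bounded store of prioritized segments.

    Capacity is counted in transitions (default 250,000). New segments enter
    at the maximum current priority so every segment is sampled at least
    once before its priority reflects actual TD errors.
    """

    def __init__(
        self,
        capacity_transitions: int = 250_000,
        segment_length: int = 10,
        eta: float = 0.9,
        schedule: PrioritySchedule | None = None,
    ):
        if segment_length < 2 or segment_length % 2 != 0:
            raise ConfigError("segment length must be even and >= 2")
        self.capacity = capacity_transitions
        self.L = segment_length
        self.eta = eta
        self.schedule = schedule or PrioritySchedule()
        self._segments: dict[int, Segment] = {}
        self._order: list[int] = []  # insertion order for FIFO eviction
        self._counter = 0
        self._episode_counter = 0

    def __len__(self) -> int:
        return len(self._segments)

    @property
    def n_transitions(self) -> int:
        return sum(s.n_valid for s in self._segments.values())

    def next_episode_id(self) -> int:
        eid = self._episode_counter
        self._episode_counter += 1
        return eid

    def add_episode(self, episode: Sequence[Transition]) -> list[int]:
        """Segmentize an episode and insert all segments; returns their ids."""
        segs = segmentize(episode, self.L)
        max_p = max((s.priority for s in self._segments.values()), default=1.0)
        ids = []
        for seg in segs:
            seg.priority = max(max_p, 1e-8)
            seg.insertion = self._counter
            self._segments[self._counter] = seg
            self._order.append(self._counter)
            ids.append(self._counter)
            self._counter += 1
        self._evict()
        return ids

    def _evict(self) -> None:
        while self.n_transitions > self.capacity and len(self._order) > 1:
            oldest = self._order.pop(0)
            del self._segments[oldest]

    def segment(self, seg_id: int) -> Segment:
        if seg_id not in self._segments:
            raise ContractError(f"unknown segment id {seg_id}")
        return self._segments[seg_id]

    def sampling_probabilities(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """(ids, probabilities) over stored segments at a training step."""
        if not self._segments:
            raise ContractError("replay store is empty")
        alpha, _ = self.schedule.exponents(step)
        ids = np.array(list(self._segments.keys()))
        pr = np.array([self._segments[i].priority for i in ids])
        scaled = np.power(np.maximum(pr, 1e-12), alpha)
        return ids, scaled / scaled.sum()

    def sample(
        self,
        batch_size: int,
        step: int,
        rng: np.random.Generator,
        with_replacement: bool = True,
    ) -> tuple[list[int], list[Segment], np.ndarray]:
        """Draw a prioritized batch of segments.

        Returns ``(ids, segments, importance_weights)``; weights are
        (N * P)^(-beta) normalized by their maximum so all are <= 1.
        """
        if len(self._segments) == 0:
            raise ContractError("replay store is empty")
        if not with_replacement and batch_size > len(self._segments):
            raise ContractError(
                f"batch size {batch_size} exceeds stored segments "
                f"{len(self._segments)}"
            )
        ids, probs = self.sampling_probabilities(step)
        _, beta = self.schedule.exponents(step)
        chosen = rng.choice(
            len(ids), size=batch_size, replace=with_replacement, p=probs
        )
        sel_ids = ids[chosen]
        sel_probs = probs[chosen]
        n = len(ids)
        weights = np.power(n * sel_probs, -beta)
        weights = weights / weights.max()
        return (
            [int(i) for i in sel_ids],
            [self._segments[int(i)] for i in sel_ids],
            weights,
        )

    def update_priorities(
        self, segment_ids: Sequence[int], deltas_per_segment: Sequence[Sequence[float]]
    ) -> None:
        """Recompute priorities from fresh n-step TD-error magnitudes."""
        if len(segment_ids) != len(deltas_per_segment):
            raise ContractError("ids and delta lists must align")
        for sid, deltas in zip(segment_ids, deltas_per_segment):
            if sid not in self._segments:
                raise ContractError(f"unknown segment id {sid}")
            self._segments[sid].priority = priority(deltas, self.eta)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist the store to an ``npz`` container for resumable runs."""
        obs, act, rew, nxt, done, eid, t, mask, prio, ins = (
            [], [], [], [], [], [], [], [], [], []
        )
        for sid in self._order:
            seg = self._segments[sid]
            obs.append([tr.observation for tr in seg.transitions])
            act.append([tr.action for tr in seg.transitions])
            rew.append([tr.reward for tr in seg.transitions])
            nxt.append([tr.next_observation for tr in seg.transitions])
            done.append([tr.done for tr in seg.transitions])
            eid.append([tr.episode_id for tr in seg.transitions])
            t.append([tr.t for tr in seg.transitions])
            mask.append(seg.mask)
            prio.append(seg.priority)
            ins.append(seg.insertion)
        np.savez_compressed(
            path,
            obs=np.array(obs), act=np.array(act), rew=np.array(rew),
            nxt=np.array(nxt), done=np.array(done), eid=np.array(eid),
            t=np.array(t), mask=np.array(mask), prio=np.array(prio),
            ins=np.array(ins),
            meta=np.array([self.capacity, self.L, self._counter,
                           self._episode_counter]),
            eta=np.array([self.eta]),
        )

    @classmethod
    def load(cls, path) -> "SegmentReplay":
        with np.load(path, allow_pickle=False) as z:
            capacity, L, counter, ep_counter = (int(v) for v in z["meta"])
            store = cls(capacity_transitions=capacity, segment_length=L,
                        eta=float(z["eta"][0]))
            for k in range(len(z["prio"])):
                trs = [
                    Transition(
                        observation=z["obs"][k, j],
                        action=z["act"][k, j],
                        reward=z["rew"][k, j],
                        next_observation=z["nxt"][k, j],
                        done=bool(z["done"][k, j]),
                        episode_id=int(z["eid"][k, j]),
                        t=int(z["t"][k, j]),
                    )
                    for j in range(L)
                ]
                seg = Segment(
                    transitions=trs,
                    mask=z["mask"][k],
                    priority=float(z["prio"][k]),
                    insertion=int(z["ins"][k]),
                )
                store._segments[seg.insertion] = seg
                store._order.append(seg.insertion)
            store._counter = counter
            store._episode_counter = ep_counter
        return store
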