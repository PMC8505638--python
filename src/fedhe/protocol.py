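"""Federated workflow orchestration over a tree of data providers.

Implements the five-step collaboration pattern: the querier sends a
cleartext query to every data provider (DP); each DP computes on its local
cleartext data and encrypts the result under the collective key; encrypted
results are aggregated up a DP tree; iterative tasks repeat the
local-compute/aggregate rounds on the encrypted state; finally the
aggregate is collectively switched to the querier's key and decrypted by
the querier alone.  Every inter-party transfer is recorded in an
append-only :class:`Transcript` so the package's information-flow claims
(nothing but ciphertext travels between DPs; exactly one final decryption,
at the querier) are mechanically checkable via :func:`audit_check`.

Parties are simulated in-process with enforced interfaces; the network
layer is out of scope and irrelevant to the information-flow semantics
under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import mhe
from .errors import ConfigurationError, DepthError, ProtocolError

__all__ = [
    "Transcript",
    "TranscriptEvent",
    "DataProvider",
    "Topology",
    "build_tree",
    "collective_aggregate",
    "audit_check",
    "AuditReport",
    "add_noise_final",
    "RefreshPolicy",
    "Collaboration",
    "setup_collaboration",
    "run_pipeline",
]

PAYLOAD_CLASSES = ("ciphertext", "public_query", "final_result")


@dataclass(frozen=True)
class TranscriptEvent:
    sender: str
    receiver: str
    step_label: str
    payload_class: str
    payload_digest: str


class Transcript:
    """Append-only audit log of every inter-party message."""

    def __init__(self) -> None:
        self._events: list[TranscriptEvent] = []

    def record(self, sender, receiver, step_label, payload_class, payload_digest="") -> None:
        if payload_class not in PAYLOAD_CLASSES:
            raise ProtocolError(f"unknown payload class {payload_class!r}")
        self._events.append(
            TranscriptEvent(str(sender), str(receiver), step_label, payload_class, payload_digest)
        )

    @property
    def events(self) -> tuple:
        return tuple(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e.__dict__) for e in self._events)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_jsonl() + ("\n" if self._events else ""))


@dataclass
class DataProvider:
    """A site holding patient-level data in cleartext, locally only."""

    dp_id: str
    local_store: object = None
    key_share: mhe.KeyShare | None = None


@dataclass
class Topology:
    """Rooted aggregation tree over all DP identifiers."""

    root_dp: str
    children: dict = field(default_factory=dict)  # dp_id -> list of child dp_ids
    fanout: int = 2

    @property
    def dp_ids(self) -> list:
        order, stack = [], [self.root_dp]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return order


def build_tree(dp_ids, fanout: int, seed: int = 0) -> Topology:
    """Deterministic balanced tree: breadth-first fill with ``fanout`` children.

    ``seed`` fixes the (otherwise arbitrary) assignment of DPs to positions.
    """
    dp_ids = list(dp_ids)
    if not dp_ids:
        raise ConfigurationError("at least one data provider is required")
    if fanout < 1:
        raise ConfigurationError("fanout must be >= 1")
    rng = np.random.default_rng(seed)
    order = [dp_ids[i] for i in rng.permutation(len(dp_ids))]
    children: dict = {dp: [] for dp in order}
    queue, idx = [order[0]], 1
    while idx < len(order):
        parent = queue.pop(0)
        for _ in range(fanout):
            if idx >= len(order):
                break
            children[parent].append(order[idx])
            queue.append(order[idx])
            idx += 1
    return Topology(root_dp=order[0], children=children, fanout=fanout)


def collective_aggregate(local_cts: dict, topology: Topology, transcript: Transcript | None = None) -> mhe.CipherVector:
    """Sum encrypted local contributions up the DP tree.

    Each DP adds its children's encrypted sums to its own encrypted local
    result and forwards the (still encrypted) sum to its parent; the root
    ends up with the element-wise total.  One transcript event per edge.
    The decrypted result is independent of the tree shape.
    """
    missing = [dp for dp in topology.dp_ids if dp not in local_cts]
    if missing:
        raise ProtocolError(f"missing contributions from DPs: {missing}")

    def subtree_sum(dp: str) -> mhe.CipherVector:
        acc = local_cts[dp]
        for child in topology.children.get(dp, []):
            child_sum = subtree_sum(child)
            if transcript is not None:
                transcript.record(child, dp, "collective_aggregation", "ciphertext", child_sum.digest())
            acc = mhe.add(acc, child_sum)
        return acc

    return subtree_sum(topology.root_dp)


@dataclass
class AuditReport:
    passed: bool
    n_events: int
    n_decryptions: int
    problems: list


def audit_check(transcript: Transcript) -> AuditReport:
    """Verify the threat-model contract on a completed transcript.

    Passes iff every payload travelling between DPs is a ciphertext, the
    only cleartext messages are the querier's public query and the final
    result delivered to the querier, and at most one decryption occurred.
    """
    problems = []
    n_dec = 0
    for ev in transcript.events:
        if ev.step_label == "decrypt":
            n_dec += 1
        if ev.payload_class == "final_result":
            if ev.receiver != "querier":
                problems.append(f"final result delivered to {ev.receiver!r}, not the querier")
        elif ev.payload_class == "public_query":
            if ev.sender != "querier":
                problems.append(f"public query sent by {ev.sender!r}, not the querier")
        elif ev.payload_class != "ciphertext":
            problems.append(f"unknown payload class {ev.payload_class!r}")
        if (
            ev.sender not in ("querier",)
            and ev.receiver not in ("querier",)
            and ev.payload_class != "ciphertext"
        ):
            problems.append(
                f"cleartext payload between parties {ev.sender!r} -> {ev.receiver!r} "
                f"at step {ev.step_label!r}"
            )
    if n_dec > 1:
        problems.append(f"{n_dec} decryption events; at most one final decryption is allowed")
    return AuditReport(passed=not problems, n_events=len(transcript), n_decryptions=n_dec, problems=problems)


def add_noise_final(result, sensitivity: float, epsilon: float, mechanism: str = "laplace",
                    delta: float = 1e-5, seed: int = 0):
    """Output perturbation for differential privacy, applied once.

    Because no intermediate value is ever decrypted, calibrated noise needs
    to be added only to the final decrypted result (not per site or per
    iteration): Laplace with scale ``sensitivity/epsilon`` for pure
    epsilon-DP, or a Gaussian calibrated to (epsilon, delta).
    """
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    if sensitivity <= 0:
        raise ConfigurationError("sensitivity must be positive")
    result = np.asarray(result, dtype=float)
    rng = np.random.default_rng(seed)
    if mechanism == "laplace":
        noise = rng.laplace(0.0, sensitivity / epsilon, size=result.shape)
    elif mechanism == "gaussian":
        if not 0 < delta < 1:
            raise ConfigurationError("gaussian mechanism requires delta in (0, 1)")
        sigma = sensitivity * np.sqrt(2.0 * np.log(1.25 / delta)) / epsilon
        noise = rng.normal(0.0, sigma, size=result.shape)
    else:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    return result + noise


class RefreshPolicy:
    """Auto-inserts collective refreshes when an operation would exhaust depth.

    Pipelines plan their multiplications through this helper so the depth
    budget is honoured without hand-placing every refresh.  Each refresh is
    an interactive round among all DPs and is logged in the transcript.
    """

    def __init__(self, shares, transcript: Transcript | None = None):
        self.shares = list(shares)
        self.transcript = transcript
        self.n_refreshes = 0

    def refresh(self, ct: mhe.CipherVector) -> mhe.CipherVector:
        self.n_refreshes += 1
        return mhe.collective_refresh(ct, self.shares, self.transcript)

    def mul(self, a: mhe.CipherVector, b) -> mhe.CipherVector:
        try:
            return mhe.mul(a, b)
        except DepthError:
            if a.depth_used > 0:
                a = self.refresh(a)
            if isinstance(b, mhe.CipherVector) and b.depth_used > 0:
                b = self.refresh(b)
            return mhe.mul(a, b)


@dataclass
class Collaboration:
    """Key material, tree and transcript shared by one federated run."""

    params: mhe.CryptoParams
    collective_key: mhe.CollectiveKey
    querier_key: mhe.QuerierKey
    shares: dict  # dp_id -> KeyShare
    topology: Topology
    transcript: Transcript
    refresher: RefreshPolicy

    @property
    def all_shares(self) -> list:
        return list(self.shares.values())


def setup_collaboration(dp_ids, params: mhe.CryptoParams | None = None, fanout: int = 2,
                        seed: int = 0) -> Collaboration:
    """Generate collective/querier keys, the DP tree, and a fresh transcript."""
    dp_ids = [str(d) for d in dp_ids]
    params = params or mhe.CryptoParams()
    if len(dp_ids) >= 2:
        ck, share_list, qk = mhe.keygen_collective(dp_ids, seed)
    else:
        # degenerate single-site run: a two-share key with a virtual co-signer
        ck, share_list, qk = mhe.keygen_collective(dp_ids + ["_virtual"], seed)
    shares = {s.party_id: s for s in share_list}
    topology = build_tree(dp_ids, fanout=fanout, seed=seed)
    transcript = Transcript()
    refresher = RefreshPolicy(list(shares.values()), transcript)
    return Collaboration(params, ck, qk, shares, topology, transcript, refresher)


def run_pipeline(query: dict, dps, querier_key, pipeline: str, config):
    """Dispatch a named pipeline over simulated DPs; returns (result, transcript).

    ``pipeline`` is one of ``km``, ``gwas_exact``, ``gwas_fast``.  Thin
    convenience wrapper over the dedicated pipeline entry points.
    """
    if pipeline == "km":
        from .survival import km_pipeline

        return km_pipeline(dps=dps, querier_key=querier_key, config=config, **query)
    if pipeline == "gwas_exact":
        from .gwas_exact import gwas_exact_pipeline

        return gwas_exact_pipeline(dps=dps, querier_key=querier_key, config=config, **query)
    if pipeline == "gwas_fast":
        from .gwas_fast import gwas_fast_pipeline

        return gwas_fast_pipeline(dps=dps, querier_key=querier_key, config=config, **query)
    raise ConfigurationError(f"unknown pipeline {pipeline!r}")
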