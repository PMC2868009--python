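"""Host-managed per-(chain, node) vector storage with double buffering.

Each allocated (chain, node) pair owns two storage slots, "pending" and
"committed". The likelihood engine writes proposal results into pending
slots; committing a proposal swaps the slot handles for the touched nodes
(an O(1) pointer swap, never a data copy), and rejecting leaves the
committed state untouched. This mirrors a co-processor whose local memory
holds two copies of every node's state, with the host swapping base
addresses on accept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Hashable, Optional

import numpy as np


class StoreUsageError(RuntimeError):
    pass


@dataclass
class NodeRecord:
    """State vectors for one tree node: conditional-likelihood table,
    scaler vector, and the transition matrix for the node's branch."""

    cond_like: Optional[np.ndarray] = None
    scaler: Any = None
    trans_matrix: Optional[np.ndarray] = None


class _Slots:
    __slots__ = ("buffers", "committed_idx", "pending_written")

    def __init__(self):
        self.buffers: list = [None, None]
        self.committed_idx = 0
        self.pending_written = False


class NodeStore:
    """Double-buffered store keyed by (chain id, node id)."""

    def __init__(self):
        self._table: dict = {}
        self.commit_copies = 0  # instrument: must stay 0 (commit never copies)

    def _key(self, chain: Hashable, node: Hashable):
        return (chain, node)

    def allocate(self, chain: Hashable, node: Hashable) -> None:
        key = self._key(chain, node)
        if key in self._table:
            raise StoreUsageError(f"duplicate allocation for {key}")
        self._table[key] = _Slots()

    def is_allocated(self, chain, node) -> bool:
        return self._key(chain, node) in self._table

    def _slots(self, chain, node) -> _Slots:
        try:
            return self._table[self._key(chain, node)]
        except KeyError:
            raise StoreUsageError(f"({chain}, {node}) not allocated") from None

    def write_pending(self, chain, node, record: NodeRecord) -> None:
        s = self._slots(chain, node)
        s.buffers[1 - s.committed_idx] = record
        s.pending_written = True

    def read_committed(self, chain, node) -> Optional[NodeRecord]:
        s = self._slots(chain, node)
        return s.buffers[s.committed_idx]

    def read_pending(self, chain, node) -> Optional[NodeRecord]:
        s = self._slots(chain, node)
        return s.buffers[1 - s.committed_idx]

    def has_pending(self, chain, node) -> bool:
        return self._slots(chain, node).pending_written

    def read_current(self, chain, node) -> Optional[NodeRecord]:
        """Pending view if written this round, else the committed record."""
        s = self._slots(chain, node)
        if s.pending_written:
            return s.buffers[1 - s.committed_idx]
        return s.buffers[s.committed_idx]

    def commit(self, chain, nodes) -> None:
        """Swap pending/committed handles for the listed nodes (no copying)."""
        for node in nodes:
            s = self._slots(chain, node)
            if s.pending_written:
                s.committed_idx = 1 - s.committed_idx
                s.pending_written = False

    def reject(self, chain) -> None:
        """Drop all pending writes for a chain; committed state is untouched."""
        for (c, _node), s in self._table.items():
            if c == chain:
                s.pending_written = False

    def nodes_for_chain(self, chain) -> list:
        return [node for (c, node) in self._table if c == chain]

    def dump(self) -> "list[dict]":
        """Plain rows for debugging / TSV export."""
        rows = []
        for (chain, node), s in self._table.items():
            rec = s.buffers[s.committed_idx]
            rows.append({
                "chain": chain, "node": node,
                "committed": rec is not None,
                "n_patterns": None if rec is None or rec.cond_like is None
                else len(rec.cond_like),
            })
        return rows
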