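"""Stimulus stream construction for statistical-learning experiments.

Streams are continuous sequences of tokens (syllables or fractal images)
presented at a fixed stimulus-onset asynchrony (SOA).  In the *structured*
condition tokens are organized into hidden units (three-syllable words or
two-fractal pairs) so that the transitional probability (TP) between
consecutive tokens is 1.0 inside a unit and ~1/3 at unit boundaries.  In the
*random* condition every token follows every other token with equal
probability, 1/(A-1) for an alphabet of A tokens.

A one-back cover task is supported by inserting occasional immediate token
repetitions ("probes") into either stream type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UnitInventory",
    "TokenStream",
    "auditory_inventory",
    "visual_inventory",
    "generate_structured_stream",
    "generate_random_stream",
    "embed_one_back_probes",
    "transition_matrix",
    "within_unit_tp",
    "between_unit_tp",
]

#: default SOA per modality, seconds per token
SOA_S = {"auditory": 0.25, "visual": 0.375}

#: on/off amplitude ramp applied to each block, seconds
RAMP_S = 1.5


@dataclass(frozen=True)
class UnitInventory:
    """The hidden units of a structured stream.

    Parameters
    ----------
    units
        Mapping from unit id to the ordered tuple of token ids that compose it.
    """

    units: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        lengths = {len(toks) for toks in self.units.values()}
        if len(lengths) != 1:
            raise ValueError("all units must have the same length")
        seen: set[str] = set()
        for toks in self.units.values():
            if seen & set(toks):
                raise ValueError("units must be disjoint")
            seen |= set(toks)

    @property
    def unit_length(self) -> int:
        return len(next(iter(self.units.values())))

    @property
    def token_alphabet(self) -> tuple[str, ...]:
        return tuple(t for toks in self.units.values() for t in toks)

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(self.units)

    def unit_of_token(self) -> dict[str, str]:
        return {t: u for u, toks in self.units.items() for t in toks}

    def position_of_token(self) -> dict[str, int]:
        """Ordinal position (1-based) of each token within its unit."""
        return {t: i + 1 for toks in self.units.values() for i, t in enumerate(toks)}


def auditory_inventory() -> UnitInventory:
    """Four tri-syllabic words over a 12-syllable alphabet."""
    return UnitInventory(
        units={
            "tupiro": ("tu", "pi", "ro"),
            "golabu": ("go", "la", "bu"),
            "bidaku": ("bi", "da", "ku"),
            "padoti": ("pa", "do", "ti"),
        }
    )


def visual_inventory() -> UnitInventory:
    """Four fractal pairs over an 8-fractal alphabet."""
    return UnitInventory(
        units={
            "pairA": ("f1", "f2"),
            "pairB": ("f3", "f4"),
            "pairC": ("f5", "f6"),
            "pairD": ("f7", "f8"),
        }
    )


@dataclass
class TokenStream:
    """A timed token sequence, possibly with hidden unit structure.

    ``unit_of``/``position_of`` hold the generating unit id and the 1-based
    ordinal position for each token (empty string / 0 in the random
    condition).  ``is_probe`` marks inserted one-back repetitions, which do not
    belong to the unit parse.
    """

    modality: str
    condition: str
    soa_s: float
    tokens: list[str]
    onsets_s: np.ndarray
    unit_of: list[str]
    position_of: np.ndarray
    is_probe: np.ndarray
    block_of: np.ndarray
    block_boundaries: np.ndarray
    inventory: UnitInventory | None = None
    ramp_s: float = RAMP_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.position_of = np.asarray(self.position_of, dtype=int)
        self.is_probe = np.asarray(self.is_probe, dtype=bool)
        self.block_of = np.asarray(self.block_of, dtype=int)
        self.block_boundaries = np.asarray(self.block_boundaries, dtype=int)
        for arr in (self.onsets_s, self.position_of, self.is_probe, self.block_of):
            if len(arr) != n:
                raise ValueError("per-token arrays must match token count")
        if n > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_blocks(self) -> int:
        return len(self.block_boundaries)

    @property
    def repeat_probes(self) -> np.ndarray:
        """Indices of inserted one-back probes."""
        return np.flatnonzero(self.is_probe)

    @property
    def duration_s(self) -> float:
        return float(self.onsets_s[-1] + self.soa_s)

    @property
    def token_alphabet(self) -> tuple[str, ...]:
        if self.inventory is not None:
            return self.inventory.token_alphabet
        return tuple(sorted(set(self.tokens)))

    def unit_onsets(self) -> np.ndarray:
        """Onset times of unit-initial (position 1) non-probe tokens."""
        if self.condition != "structured":
            raise ValueError("unit onsets are defined for structured streams only")
        mask = (self.position_of == 1) & ~self.is_probe
        return self.onsets_s[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "token": self.tokens,
                "onset_s": self.onsets_s,
                "unit": self.unit_of,
                "position": self.position_of,
                "is_probe": self.is_probe.astype(int),
                "block": self.block_of,
            }
        )

    def save(self, path: str | Path) -> None:
        """Write the stream as TSV plus a JSON design sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {
            "modality": self.modality,
            "condition": self.condition,
            "soa_s": self.soa_s,
            "ramp_s": self.ramp_s,
            "block_boundaries": self.block_boundaries.tolist(),
            "units": (
                {u: list(t) for u, t in self.inventory.units.items()}
                if self.inventory
                else None
            ),
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TokenStream":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"token": str, "unit": str})
        sidecar = json.loads(path.with_suffix(".json").read_text())
        inventory = None
        if sidecar.get("units"):
            inventory = UnitInventory(
                units={u: tuple(t) for u, t in sidecar["units"].items()}
            )
        return cls(
            modality=sidecar["modality"],
            condition=sidecar["condition"],
            soa_s=sidecar["soa_s"],
            tokens=df["token"].tolist(),
            onsets_s=df["onset_s"].to_numpy(),
            unit_of=df["unit"].fillna("").tolist(),
            position_of=df["position"].to_numpy(),
            is_probe=df["is_probe"].to_numpy().astype(bool),
            block_of=df["block"].to_numpy(),
            block_boundaries=np.asarray(sidecar["block_boundaries"]),
            inventory=inventory,
            ramp_s=sidecar.get("ramp_s", RAMP_S),
            meta=sidecar.get("meta", {}),
        )


def _balanced_counts(n_slots: int, n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``n_slots`` across ``n_items`` as evenly as possible (max spread 1)."""
    base, extra = divmod(n_slots, n_items)
    counts = np.full(n_items, base, dtype=int)
    counts[rng.choice(n_items, size=extra, replace=False)] += 1
    return counts


def _sequence_no_repeat(
    counts: np.ndarray, rng: np.random.Generator, prev: int | None, max_restarts: int = 1000
) -> list[int]:
    """Draw a sequence consuming ``counts`` of each item id, uniformly among the
    items legal at each step (any item with remaining count except the previous
    one).  Restarts on dead ends, which are rare for >= 3 items."""
    n_items = len(counts)
    if n_items < 2 and counts.sum() > 1:
        raise ValueError(
            "cannot build a no-immediate-repetition sequence from a single item"
        )
    for _ in range(max_restarts):
        remaining = counts.copy()
        seq: list[int] = []
        last = prev
        ok = True
        while remaining.sum() > 0:
            legal = np.flatnonzero(remaining > 0)
            if last is not None:
                legal = legal[legal != last]
            if len(legal) == 0:
                ok = False
                break
            pick = int(rng.choice(legal))
            seq.append(pick)
            remaining[pick] -= 1
            last = pick
        if ok:
            return seq
    raise RuntimeError("failed to draw a no-repetition sequence")


def _infer_modality(inventory_or_alphabet) -> str:
    n = (
        len(inventory_or_alphabet.token_alphabet)
        if isinstance(inventory_or_alphabet, UnitInventory)
        else len(inventory_or_alphabet)
    )
    return "auditory" if n >= 12 else "visual"


def generate_structured_stream(
    inventory: UnitInventory,
    n_blocks: int = 5,
    block_tokens: int = 540,
    seed: int | np.random.Generator = 0,
    soa_s: float | None = None,
    modality: str | None = None,
) -> TokenStream:
    """Generate a structured stream of hidden units.

    Units are sampled uniformly with no immediate unit repetition and balanced
    counts per block (+/-1), so the TP from a unit-final token to a specific
    other unit's initial token converges to 1/(n_units - 1) = 1/3 for four
    units, while within-unit TPs are exactly 1.
    """
    if block_tokens % inventory.unit_length != 0:
        raise ValueError(
            f"block_tokens={block_tokens} is not divisible by unit_length="
            f"{inventory.unit_length} (remainder {block_tokens % inventory.unit_length})"
        )
    if len(inventory.units) < 2:
        raise ValueError(
            "structured generation needs >= 2 units: with a single unit the "
            "no-immediate-repetition rule leaves no legal successor"
        )
    rng = np.random.default_rng(seed)
    modality = modality or _infer_modality(inventory)
    soa = soa_s if soa_s is not None else SOA_S[modality]
    unit_ids = inventory.unit_ids
    units_per_block = block_tokens // inventory.unit_length

    tokens: list[str] = []
    unit_of: list[str] = []
    position_of: list[int] = []
    block_of: list[int] = []
    boundaries: list[int] = []
    prev: int | None = None
    for b in range(n_blocks):
        boundaries.append(len(tokens))
        counts = _balanced_counts(units_per_block, len(unit_ids), rng)
        for u_idx in _sequence_no_repeat(counts, rng, prev):
            uid = unit_ids[u_idx]
            for pos, tok in enumerate(inventory.units[uid], start=1):
                tokens.append(tok)
                unit_of.append(uid)
                position_of.append(pos)
                block_of.append(b)
            prev = u_idx

    n = len(tokens)
    return TokenStream(
        modality=modality,
        condition="structured",
        soa_s=soa,
        tokens=tokens,
        onsets_s=np.arange(n) * soa,
        unit_of=unit_of,
        position_of=np.array(position_of),
        is_probe=np.zeros(n, dtype=bool),
        block_of=np.array(block_of),
        block_boundaries=np.array(boundaries),
        inventory=inventory,
    )


def generate_random_stream(
    alphabet,
    n_blocks: int = 5,
    block_tokens: int = 540,
    seed: int | np.random.Generator = 0,
    soa_s: float | None = None,
    modality: str | None = None,
) -> TokenStream:
    """Generate a random stream with uniform transitional probabilities.

    Each successor is drawn uniformly from the alphabet excluding the current
    token, yielding TP = 1/(A-1) for every ordered token pair (1/11 for 12
    syllables, 1/7 for 8 fractals).  Token counts are balanced per block (+/-1).
    """
    inventory = None
    if isinstance(alphabet, UnitInventory):
        inventory = alphabet
        alphabet = alphabet.token_alphabet
    alphabet = list(alphabet)
    if len(alphabet) < 2:
        raise ValueError("random stream needs an alphabet of >= 2 tokens")
    rng = np.random.default_rng(seed)
    modality = modality or _infer_modality(alphabet)
    soa = soa_s if soa_s is not None else SOA_S[modality]

    tokens: list[str] = []
    block_of: list[int] = []
    boundaries: list[int] = []
    prev: int | None = None
    for b in range(n_blocks):
        boundaries.append(len(tokens))
        counts = _balanced_counts(block_tokens, len(alphabet), rng)
        for t_idx in _sequence_no_repeat(counts, rng, prev):
            tokens.append(alphabet[t_idx])
            block_of.append(b)
            prev = t_idx

    n = len(tokens)
    return TokenStream(
        modality=modality,
        condition="random",
        soa_s=soa,
        tokens=tokens,
        onsets_s=np.arange(n) * soa,
        unit_of=[""] * n,
        position_of=np.zeros(n, dtype=int),
        is_probe=np.zeros(n, dtype=bool),
        block_of=np.array(block_of),
        block_boundaries=np.array(boundaries),
        inventory=inventory,
    )


def embed_one_back_probes(
    stream: TokenStream,
    n_per_block: int = 16,
    seed: int | np.random.Generator = 0,
    min_gap: int = 3,
) -> TokenStream:
    """Insert one-back repetition probes for the cover task.

    ``n_per_block`` immediate repetitions are inserted at uniformly chosen
    positions in each block, with a minimum spacing of ``min_gap`` tokens
    between probes and none inside the first/last ``ramp_s`` of a block (the
    amplitude ramp would cue them).  Onsets are recomputed on the fixed SOA
    grid; the relative order and unit parse of all non-probe tokens is
    unchanged.
    """
    if n_per_block < 0:
        raise ValueError("n_per_block must be >= 0")
    if n_per_block == 0:
        out = replace(stream)
        out.meta = {**stream.meta, "probes_per_block": 0}
        return out
    rng = np.random.default_rng(seed)
    edge_tokens = int(np.ceil(stream.ramp_s / stream.soa_s))

    # chosen[i] == k means: insert k copies of tokens[i] right after position i
    insert_after: dict[int, int] = {}
    bounds = list(stream.block_boundaries) + [len(stream)]
    for b in range(stream.n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        candidates = np.arange(lo + edge_tokens, hi - edge_tokens)
        chosen: list[int] = []
        order = rng.permutation(candidates)
        for idx in order:
            if all(abs(idx - c) > min_gap for c in chosen):
                chosen.append(int(idx))
            if len(chosen) == n_per_block:
                break
        if len(chosen) < n_per_block:
            raise ValueError(
                f"block {b}: only {len(chosen)} legal probe slots for "
                f"{n_per_block} probes (min_gap={min_gap}, edge={edge_tokens} tokens)"
            )
        for idx in chosen:
            insert_after[idx] = insert_after.get(idx, 0) + 1

    tokens: list[str] = []
    unit_of: list[str] = []
    position_of: list[int] = []
    is_probe: list[bool] = []
    block_of: list[int] = []
    boundaries: list[int] = []
    seen_blocks: set[int] = set()
    for i, tok in enumerate(stream.tokens):
        b = int(stream.block_of[i])
        if b not in seen_blocks:
            boundaries.append(len(tokens))
            seen_blocks.add(b)
        tokens.append(tok)
        unit_of.append(stream.unit_of[i])
        position_of.append(int(stream.position_of[i]))
        is_probe.append(bool(stream.is_probe[i]))
        block_of.append(b)
        for _ in range(insert_after.get(i, 0)):
            tokens.append(tok)
            unit_of.append(stream.unit_of[i])
            position_of.append(int(stream.position_of[i]))
            is_probe.append(True)
            block_of.append(b)

    n = len(tokens)
    return TokenStream(
        modality=stream.modality,
        condition=stream.condition,
        soa_s=stream.soa_s,
        tokens=tokens,
        onsets_s=np.arange(n) * stream.soa_s,
        unit_of=unit_of,
        position_of=np.array(position_of),
        is_probe=np.array(is_probe),
        block_of=np.array(block_of),
        block_boundaries=np.array(boundaries),
        inventory=stream.inventory,
        ramp_s=stream.ramp_s,
        meta={**stream.meta, "probes_per_block": n_per_block},
    )


def transition_matrix(
    stream: TokenStream, exclude_probes: bool = True
) -> pd.DataFrame:
    """Empirical first-order transitional probability matrix P(col | row).

    Transitions across block boundaries are excluded; probe insertions are
    dropped from the sequence before counting by default, restoring the
    underlying token order.
    """
    alphabet = list(stream.token_alphabet)
    index = {t: i for i, t in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), len(alphabet)))
    keep = ~stream.is_probe if exclude_probes else np.ones(len(stream), dtype=bool)
    toks = [t for t, k in zip(stream.tokens, keep) if k]
    blocks = stream.block_of[keep]
    for i in range(len(toks) - 1):
        if blocks[i] != blocks[i + 1]:
            continue
        counts[index[toks[i]], index[toks[i + 1]]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(row_sums > 0, counts / row_sums, 0.0)
    return pd.DataFrame(tp, index=alphabet, columns=alphabet)


def within_unit_tp(stream: TokenStream) -> float:
    """Mean empirical TP over all within-unit (non-final -> next) transitions."""
    if stream.inventory is None:
        raise ValueError("stream has no unit inventory")
    tp = transition_matrix(stream)
    vals = []
    for toks in stream.inventory.units.values():
        for a, b in zip(toks[:-1], toks[1:]):
            vals.append(tp.loc[a, b])
    return float(np.mean(vals))


def between_unit_tp(stream: TokenStream) -> float:
    """Mean empirical TP from unit-final tokens to other units' initial tokens.

    Self-transitions (a unit immediately repeating) are structurally absent and
    excluded, so for four units the expected value is 1/3.
    """
    if stream.inventory is None:
        raise ValueError("stream has no unit inventory")
    tp = transition_matrix(stream)
    units = stream.inventory.units
    vals = []
    for u_from, toks_from in units.items():
        for u_to, toks_to in units.items():
            if u_from == u_to:
                continue
            vals.append(tp.loc[toks_from[-1], toks_to[0]])
    return float(np.mean(vals))
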