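"""TMT plex design across SEC fractions.

Each SEC fraction is one 11-plex TMT set: nine sample channels (three
conditions x three replicates), one reference channel (a pooled mix of all
samples before SEC) and one empty channel.  The channel-to-sample assignment
may rotate from fraction to fraction; every downstream module resolves
channels through the :class:`PlexDesign` of the PSM's fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DesignError, FormatError

TMT11_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131N", "131C",
)

CONDITIONS: tuple[str, ...] = ("L", "L+N", "L+V")
REPLICATES: tuple[int, ...] = (1, 2, 3)
#: canonical sample column order used by every quantification matrix
SAMPLES: tuple[str, ...] = tuple(
    f"{c}_{r}" for c in CONDITIONS for r in REPLICATES
)


def sample_id(condition: str, replicate: int) -> str:
    return f"{condition}_{replicate}"


def condition_of(sample: str) -> str:
    return sample.rsplit("_", 1)[0]


@dataclass(frozen=True)
class ChannelRole:
    """Role of one TMT channel: sample (condition, replicate), reference or empty."""

    kind: str  # "sample" | "reference" | "empty"
    condition: str | None = None
    replicate: int | None = None

    @property
    def sample(self) -> str | None:
        if self.kind != "sample":
            return None
        return sample_id(self.condition, self.replicate)


@dataclass
class PlexDesign:
    """Channel -> role mapping for one SEC fraction (ordered)."""

    fraction_id: int
    roles: dict[str, ChannelRole]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.roles)

    @property
    def reference_channel(self) -> str:
        return next(c for c, r in self.roles.items() if r.kind == "reference")

    @property
    def empty_channel(self) -> str:
        return next(c for c, r in self.roles.items() if r.kind == "empty")

    @property
    def sample_channels(self) -> dict[str, str]:
        """Ordered channel label -> sample id for the nine sample channels."""
        return {c: r.sample for c, r in self.roles.items() if r.kind == "sample"}

    def validate(self) -> None:
        if self.fraction_id < 1:
            raise DesignError(f"fraction_id must be >= 1, got {self.fraction_id}")
        kinds = [r.kind for r in self.roles.values()]
        if kinds.count("reference") != 1:
            raise DesignError(
                f"fraction {self.fraction_id}: expected exactly one reference "
                f"channel, found {kinds.count('reference')}"
            )
        if kinds.count("empty") != 1:
            raise DesignError(
                f"fraction {self.fraction_id}: expected exactly one empty "
                f"channel, found {kinds.count('empty')}"
            )
        pairs = [
            (r.condition, r.replicate)
            for r in self.roles.values()
            if r.kind == "sample"
        ]
        expected = {(c, r) for c in CONDITIONS for r in REPLICATES}
        if len(pairs) != len(expected) or set(pairs) != expected:
            missing = sorted(expected - set(pairs))
            extra = sorted(set(pairs) - expected)
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise DesignError(
                f"fraction {self.fraction_id}: sample channels must cover each "
                f"(condition, replicate) pair exactly once; "
                f"missing={missing} extra={extra} duplicated={dupes}"
            )


def rotated_design(
    n_fractions: int = 21,
    channels: tuple[str, ...] = TMT11_CHANNELS,
    rotate: bool = True,
) -> dict[int, PlexDesign]:
    """Build a design where the role layout rotates by one channel per fraction,
    emulating channel rotation across TMT sets."""
    base: list[ChannelRole] = [
        ChannelRole("sample", c, r) for c in CONDITIONS for r in REPLICATES
    ]
    base.append(ChannelRole("reference"))
    base.append(ChannelRole("empty"))
    if len(base) != len(channels):
        raise DesignError(
            f"need {len(base)} channels for this layout, got {len(channels)}"
        )
    designs: dict[int, PlexDesign] = {}
    n = len(channels)
    for f in range(1, n_fractions + 1):
        shift = (f - 1) % n if rotate else 0
        roles = {
            channels[i]: base[(i - shift) % n] for i in range(n)
        }
        designs[f] = PlexDesign(f, roles)
    return designs


_DESIGN_COLUMNS = ("fraction", "channel", "role", "condition", "replicate")


def read_design(path) -> dict[int, PlexDesign]:
    """Read a design TSV (fraction, channel, role, condition, replicate).

    Returns one :class:`PlexDesign` per fraction with invariants enforced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing column(s): {', '.join(missing)}")
    designs: dict[int, PlexDesign] = {}
    for frac, block in df.groupby("fraction", sort=True):
        roles: dict[str, ChannelRole] = {}
        for _, row in block.iterrows():
            kind = row["role"].strip()
            if kind == "sample":
                role = ChannelRole(
                    "sample", row["condition"], int(float(row["replicate"]))
                )
            elif kind in ("reference", "empty"):
                role = ChannelRole(kind)
            else:
                raise DesignError(f"unknown channel role {kind!r}")
            if row["channel"] in roles:
                raise DesignError(
                    f"fraction {frac}: duplicate channel {row['channel']!r}"
                )
            roles[row["channel"]] = role
        designs[int(frac)] = PlexDesign(int(frac), roles)
    return dict(sorted(designs.items()))


def write_design(designs: dict[int, PlexDesign], path) -> None:
    rows = []
    for f, d in sorted(designs.items()):
        for channel, role in d.roles.items():
            rows.append(
                {
                    "fraction": f,
                    "channel": channel,
                    "role": role.kind,
                    "condition": role.condition or "",
                    "replicate": role.replicate if role.replicate is not None else "",
                }
            )
    pd.DataFrame(rows, columns=list(_DESIGN_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
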