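"""Filter-funnel accounting: per-stage in/out counts with reason codes.

Every filtering stage appends an entry; ``validate`` checks that counts never
grow, that dropped records are fully attributed to reason codes, and that
adjacent chained stages agree (out of stage k == in of stage k+1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class FunnelStage:
    name: str
    records_in: int
    records_out: int
    reasons: dict[str, int] = field(default_factory=dict)


class FunnelError(ValueError):
    pass


class FunnelReport:
    def __init__(self) -> None:
        self.stages: list[FunnelStage] = []

    def add(self, name: str, records_in: int, records_out: int, reasons: dict[str, int] | None = None) -> None:
        self.stages.append(FunnelStage(name, records_in, records_out, dict(reasons or {})))

    def validate(self, chained: bool = True) -> None:
        for st in self.stages:
            if st.records_out > st.records_in:
                raise FunnelError(f"stage {st.name}: out {st.records_out} > in {st.records_in}")
            dropped = st.records_in - st.records_out
            attributed = sum(st.reasons.values())
            if attributed != dropped:
                raise FunnelError(
                    f"stage {st.name}: {dropped} dropped but {attributed} attributed to reasons"
                )
        if chained:
            for a, b in zip(self.stages, self.stages[1:]):
                if a.records_out != b.records_in:
                    raise FunnelError(
                        f"stages do not chain: {a.name} out {a.records_out} != "
                        f"{b.name} in {b.records_in}"
                    )

    def to_dict(self) -> list[dict]:
        return [asdict(s) for s in self.stages]

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FunnelReport":
        rep = cls()
        for d in json.loads(Path(path).read_text()):
            rep.add(d["name"], d["records_in"], d["records_out"], d.get("reasons"))
        return rep
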