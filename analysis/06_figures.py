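#!/usr/bin/env python
"""Growth-curve and anomaly figures from a full deterministic run."""

from pathlib import Path

from crossfence.pipeline import make_figures, run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    art = run_pipeline()
    written = make_figures(art, ROOT / "figures")
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
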