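"""Regenerate the synthetic WPP-like schedule fixtures shipped with lingcast.

Run from the repository root:

    python scripts/make_fixtures.py
"""

from pathlib import Path

from lingcast import synthetic_data
from lingcast.formats_io import write_fertility_table, write_mortality_schedule


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "lingcast" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    schedule = synthetic_data.make_synthetic_lifetable()
    write_mortality_schedule(schedule, data_dir / "synthetic_lifetable.csv")
    fertility = synthetic_data.make_synthetic_fertility()
    write_fertility_table(fertility, data_dir / "synthetic_fertility.csv")
    print(f"wrote fixtures to {data_dir}")


if __name__ == "__main__":
    main()
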