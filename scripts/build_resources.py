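"""Regenerate the bundled package resources from the synthetic generator.

Run from the repository root:  python scripts/build_resources.py

Writes (deterministically) into src/isopeptide_detect/data/:
  templates/          six ideal-geometry triad templates
  geometry_reference.tsv   reference bond-geometry samples (synthetic)
  default_model.txt   logistic model fitted on simulated site features
"""
from pathlib import Path

from isopeptide_detect.classifier import train
from isopeptide_detect.synthetic import (
    default_template_library,
    simulate_training_features,
    write_reference_file,
)
from isopeptide_detect.templates import save_library

DATA = Path(__file__).resolve().parent.parent / "src" / "isopeptide_detect" / "data"


def main() -> None:
    save_library(default_template_library(), DATA / "templates")
    write_reference_file(DATA / "geometry_reference.tsv")
    positives, negatives = simulate_training_features()
    model = train(positives, negatives, seed=2024)
    model.training_meta["source"] = "synthetic-feature-simulation-seed2024"
    model.save(DATA / "default_model.txt")
    print(f"resources written under {DATA}")


if __name__ == "__main__":
    main()
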