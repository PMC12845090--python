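"""Regenerate the shipped example data files under src/wdindex/data/.

The files are synthetic and NON-AUTHORITATIVE: they illustrate the file
formats and support tests/demos.  The "global" reference statistics are the
population statistics of an independently simulated reference cohort
(fixed seed), standing in for external consumption-database statistics.
"""

from pathlib import Path

from wdindex import io, mets, scoring, synthetic

DATA = Path(__file__).resolve().parents[1] / "src" / "wdindex" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    schema = synthetic.default_schema()
    io.write_schema(
        schema,
        DATA / "example_schema.yaml",
        header="Example component schema (synthetic, NON-AUTHORITATIVE)",
    )
    io.write_coefficients(
        synthetic.example_coefficients(schema),
        DATA / "example_coefficients.csv",
        header="NON-AUTHORITATIVE example coefficients (synthetic illustration only)",
    )
    # independent synthetic reference cohort -> "global" statistics
    cfg = synthetic.default_generator_config(n_subjects=4000, seed=314159)
    ref_cohort = synthetic.generate(cfg)
    pop = scoring.compute_population_stats(ref_cohort.intakes, schema)
    global_ref = type(pop)(mean=pop.mean, sd=pop.sd, source="global")
    io.write_reference_stats(
        global_ref,
        DATA / "example_global_stats.csv",
        header="Synthetic global reference statistics (NON-AUTHORITATIVE)",
    )
    io.write_rulesets(mets.default_rulesets(), DATA / "default_rulesets.yaml")
    print("wrote example data to", DATA)


if __name__ == "__main__":
    main()
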