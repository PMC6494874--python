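Frozen independent-oracle provenance.

The deterministic 40-row fixture used by the REML cross-check in
`tests/test_meta_model.py` is regenerated in-test from numpy seed
20240917. To reproduce the frozen expected values, dump that fixture to
`metafor_fixture.csv` in this directory (the test module has a
`_fixture_frame()` helper) and run:

    Rscript metafor_oracle.R

The printed metafor::rma.mv estimates are the ones frozen in the test.
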