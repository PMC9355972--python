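Place the COSMIC Ver. 2 signature probability file here as
`cosmic_v2_signatures.tsv` (tab-separated, 96 channel rows x 30
signature columns, as downloaded from COSMIC) to enable the
COSMIC-dependent checks in `tests/test_acceptance.py` and the extra
quantities in `scripts/acceptance.py`. The file is not bundled because
COSMIC data are not redistributable with this package.
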