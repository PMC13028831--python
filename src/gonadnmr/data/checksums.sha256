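af49a377e0c2d18b1b82035b207f645fdab48cd88cd0885388f60ddd7b69890f  polar_peaks.csv
1406ccc49b4efbbd2f8d23f6f94dc416a0e278ffa592a4ff9615e5fc531e5495  apolar_peaks.csv
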