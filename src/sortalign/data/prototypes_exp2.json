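{"version": 1, "note": "Synthetic point-stimulus prototypes: 39-point circle and square outlines, unit bounding box.", "prototypes": [{"shape_id": "proto-A", "category": "A", "role": "prototype", "distortion": "none", "vertices": [[0.999189, 0.5], [0.992709, 0.580271], [0.973436, 0.658463], [0.941871, 0.73255], [0.898829, 0.800615], [0.845426, 0.860894], [0.783046, 0.911826], [0.713303, 0.952092], [0.638005, 0.980649], [0.5591, 0.996757], [0.478634, 1.0], [0.398689, 0.990293], [0.321337, 0.967888], [0.24858, 0.933364], [0.182304, 0.887617], [0.124224, 0.83183], [0.075845, 0.76745], [0.03842, 0.696142], [0.012918, 0.619755], [0.0, 0.540266], [0.0, 0.459734], [0.012918, 0.380245], [0.03842, 0.303858], [0.075845, 0.23255], [0.124224, 0.16817], [0.182304, 0.112383], [0.24858, 0.066636], [0.321337, 0.032112], [0.398689, 0.009707], [0.478634, 0.0], [0.5591, 0.003243], [0.638005, 0.019351], [0.713303, 0.047908], [0.783046, 0.088174], [0.845426, 0.139106], [0.898829, 0.199385], [0.941871, 0.26745], [0.973436, 0.341537], [0.992709, 0.419729]], "contour": null, "seen_in_preexposure": false}, {"shape_id": "proto-B", "category": "B", "role": "prototype", "distortion": "none", "vertices": [[0.0, 0.0], [0.102564, 0.0], [0.205128, 0.0], [0.307692, 0.0], [0.410256, 0.0], [0.512821, 0.0], [0.615385, 0.0], [0.717949, 0.0], [0.820513, 0.0], [0.923077, 0.0], [1.0, 0.025641], [1.0, 0.128205], [1.0, 0.230769], [1.0, 0.333333], [1.0, 0.435897], [1.0, 0.538462], [1.0, 0.641026], [1.0, 0.74359], [1.0, 0.846154], [1.0, 0.948718], [0.948718, 1.0], [0.846154, 1.0], [0.74359, 1.0], [0.641026, 1.0], [0.538462, 1.0], [0.435897, 1.0], [0.333333, 1.0], [0.230769, 1.0], [0.128205, 1.0], [0.025641, 1.0], [0.0, 0.923077], [0.0, 0.820513], [0.0, 0.717949], [0.0, 0.615385], [0.0, 0.512821], [0.0, 0.410256], [0.0, 0.307692], [0.0, 0.205128], [0.0, 0.102564]], "contour": null, "seen_in_preexposure": false}]}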