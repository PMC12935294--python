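term	disease
Thymoma	thymoma
Thymoma malignant	thymoma
Thymoma malignant recurrent	thymoma
Malignant thymoma	thymoma
Thymic carcinoma	thymic_carcinoma
Thymic cancer	thymic_carcinoma
Thymus cancer	thymic_carcinoma
Thymus carcinoma	thymic_carcinoma
Thymic carcinoma metastatic	thymic_carcinoma
Thymic carcinoma recurrent	thymic_carcinoma
Thymic neuroendocrine tumour	thymic_NET
Thymic neuroendocrine tumor	thymic_NET
Neuroendocrine carcinoma of the thymus	thymic_NET
Thymic neoplasm	unspecified_TET
Thymus neoplasm	unspecified_TET
Thymic epithelial tumour	unspecified_TET
Thymic epithelial tumor	unspecified_TET
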