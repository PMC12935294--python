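name	ingredient	drug_class
NIVOLUMAB	NIVOLUMAB	anti_PD1
OPDIVO	NIVOLUMAB	anti_PD1
PEMBROLIZUMAB	PEMBROLIZUMAB	anti_PD1
KEYTRUDA	PEMBROLIZUMAB	anti_PD1
SINTILIMAB	SINTILIMAB	anti_PD1
TYVYT	SINTILIMAB	anti_PD1
PENPULIMAB	PENPULIMAB	anti_PD1
TISLELIZUMAB	TISLELIZUMAB	anti_PD1
TEVIMBRA	TISLELIZUMAB	anti_PD1
TORIPALIMAB	TORIPALIMAB	anti_PD1
LOQTORZI	TORIPALIMAB	anti_PD1
CAMRELIZUMAB	CAMRELIZUMAB	anti_PD1
CEMIPLIMAB	CEMIPLIMAB	anti_PD1
LIBTAYO	CEMIPLIMAB	anti_PD1
ATEZOLIZUMAB	ATEZOLIZUMAB	anti_PDL1
TECENTRIQ	ATEZOLIZUMAB	anti_PDL1
AVELUMAB	AVELUMAB	anti_PDL1
BAVENCIO	AVELUMAB	anti_PDL1
DURVALUMAB	DURVALUMAB	anti_PDL1
IMFINZI	DURVALUMAB	anti_PDL1
IPILIMUMAB	IPILIMUMAB	anti_CTLA4
YERVOY	IPILIMUMAB	anti_CTLA4
TREMELIMUMAB	TREMELIMUMAB	anti_CTLA4
IMJUDO	TREMELIMUMAB	anti_CTLA4
CARBOPLATIN	CARBOPLATIN	chemotherapy
CISPLATIN	CISPLATIN	chemotherapy
PACLITAXEL	PACLITAXEL	chemotherapy
NAB-PACLITAXEL	PACLITAXEL	chemotherapy
PEMETREXED	PEMETREXED	chemotherapy
ALIMTA	PEMETREXED	chemotherapy
ETOPOSIDE	ETOPOSIDE	chemotherapy
DOCETAXEL	DOCETAXEL	chemotherapy
GEMCITABINE	GEMCITABINE	chemotherapy
CYCLOPHOSPHAMIDE	CYCLOPHOSPHAMIDE	chemotherapy
DOXORUBICIN	DOXORUBICIN	chemotherapy
FLUOROURACIL	FLUOROURACIL	chemotherapy
CAPECITABINE	CAPECITABINE	chemotherapy
VINORELBINE	VINORELBINE	chemotherapy
LENVATINIB	LENVATINIB	targeted
LENVIMA	LENVATINIB	targeted
SUNITINIB	SUNITINIB	targeted
SUTENT	SUNITINIB	targeted
EVEROLIMUS	EVEROLIMUS	targeted
AFINITOR	EVEROLIMUS	targeted
SORAFENIB	SORAFENIB	targeted
APATINIB	APATINIB	targeted
ANLOTINIB	ANLOTINIB	targeted
BEVACIZUMAB	BEVACIZUMAB	targeted
AVASTIN	BEVACIZUMAB	targeted
OCTREOTIDE	OCTREOTIDE	targeted
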