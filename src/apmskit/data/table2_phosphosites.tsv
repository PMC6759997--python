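position	peptide	species	source	identified_in
T6	MMRQAtMDFSTPS	Human	PhosphoSitePlus	N/T
T11	QATMDFStPSVFDQQ	Human	PhosphoSitePlus
T189	GADPtLVDK	Human	dbPAF
S436	TQsLPPITLGNNFLTASHR	Human	dbPAF	T
S473	MAQRSQKsRSEQDLL	Mouse	PhosphoSitePlus
S475	QRSQKSRsEQDLLNN	Mouse	PhosphoSitePlus	N/T
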