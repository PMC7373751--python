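study_id,n_control,n_case,country,year
GSE7329,15,15,USA,2007
GSE15402a,29,26,USA,2009
GSE15402b,29,30,USA,2009
GSE15451,17,21,USA,2009
GSE25507,64,82,USA,2011
GSE26415,42,21,Japan,2011
GSE28521,40,39,USA,2011
GSE29691,13,2,Saudi Arabia,2014
GSE37772,206,233,USA,2012
GSE38322,18,18,USA,2012
GSE42133,56,91,USA,2015
GSE62632,12,6,USA,2014
GSE63524,5,6,France,2014
GSE65106,38,21,USA,2017
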