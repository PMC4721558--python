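case_id,tma_id,year,histology,grade,ck_cocktail,er,pr,her2,ck56,egfr,ki67_percent,printed_phenotype
1-1,TMA1,1955,Invasive carcinoma with ductal and lobular features,2,pos,pos,neg,neg,neg,neg,1.3,Luminal A
1-1,TMA2,1955,Invasive carcinoma with ductal and lobular features,2,pos,pos,neg,neg,neg,neg,0.3,Luminal A
1-2,TMA1,1957,IDC,2,pos,pos,pos,3+,neg,neg,9.0,Luminal B
1-2,TMA2,1957,IDC,2,pos,pos,pos,3+,neg,neg,4.7,Luminal B
1-3,TMA1,1959,IDC,3,pos,pos,pos,neg,neg,neg,2.7,Luminal A
1-3,TMA2,1959,IDC,3,pos,pos,pos,neg,neg,neg,5.3,Luminal A
1-4,TMA1,1956,Invasive lobular carcinoma,2,pos,pos,pos,neg,neg,neg,1.3,Luminal A
1-4,TMA2,1956,Invasive lobular carcinoma,2,pos,pos,pos,neg,neg,neg,2.0,Luminal A
1-5,TMA1,1956,IDC,3,neg,neg,neg,neg,neg,neg,12.3,Unclassifiable
1-5,TMA2,1956,IDC,3,neg,neg,neg,neg,neg,neg,12.7,Unclassifiable
2-6,TMA1,1968,Solid papillary carcinoma,2,pos,pos,pos,neg,neg,neg,3.0,Luminal A
2-6,TMA2,1968,Solid papillary carcinoma,2,pos,pos,pos,neg,neg,neg,3.3,Luminal A
2-7,TMA1,1969,IDC,3,pos,neg,neg,2+,neg,pos,23.0,Basal-like
2-7,TMA2,1969,IDC,3,pos,neg,neg,2+,neg,neg,18.0,Unclassifiable
2-8,TMA1,1969,IDC,2,pos,pos,pos,3+,neg,neg,9.0,Luminal B
2-8,TMA2,1969,IDC,2,pos,pos,pos,3+,neg,neg,5.7,Luminal B
2-9,TMA1,1968,Invasive mucinous carcinoma,2,neg,pos,pos,neg,neg,neg,2.7,Luminal A
2-9,TMA2,1968,Invasive mucinous carcinoma,2,neg,pos,pos,neg,neg,neg,4.0,Luminal A
2-10,TMA1,1965,IDC with medullary features,3,pos,neg,neg,neg,neg,pos,7.0,Basal-like
2-10,TMA2,1965,IDC with medullary features,3,pos,neg,neg,neg,pos,pos,5.0,Basal-like
3-11,TMA1,1973,IDC,1,pos,pos,pos,neg,neg,neg,6.0,Luminal A
3-11,TMA2,1973,IDC,1,pos,pos,pos,neg,neg,neg,4.7,Luminal A
3-12,TMA1,1974,IDC,3,pos,pos,pos,neg,neg,neg,6.0,Luminal A
3-12,TMA2,1974,IDC,3,pos,pos,pos,neg,neg,neg,7.3,Luminal A
3-13,TMA1,1977,IDC,3,NA,NA,NA,NA,NA,NA,NA,NA
3-13,TMA2,1977,IDC,3,pos,pos,pos,neg,neg,neg,16.3,Luminal B
3-14,TMA1,1979,Solid papillary carcinoma,2,pos,pos,pos,neg,pos,neg,1.7,Luminal A
3-14,TMA2,1979,Solid papillary carcinoma,2,pos,pos,pos,neg,pos,neg,2.5,Luminal A
3-15,TMA1,1974,IDC,3,pos,neg,neg,3+,pos,neg,8.7,HER2
3-15,TMA2,1974,IDC,3,pos,neg,neg,3+,neg,neg,8.0,HER2
4-16,TMA1,1988,IDC,3,pos,pos,pos,neg,neg,neg,2.0,Luminal A
4-16,TMA2,1988,IDC,3,pos,pos,pos,neg,neg,neg,2.0,Luminal A
4-17,TMA1,1980,IDC,3,pos,neg,neg,neg,neg,neg,9.7,Unclassifiable
4-17,TMA2,1980,IDC,3,pos,neg,neg,neg,neg,neg,7.3,Unclassifiable
4-18,TMA1,1985,IDC,3,pos,pos,pos,neg,neg,neg,10.0,Luminal A
4-18,TMA2,1985,IDC,3,pos,pos,neg,neg,neg,neg,3.5,Luminal A
4-19,TMA1,1986,Tubular carcinoma,1,pos,pos,neg,neg,neg,neg,1.3,Luminal A
4-19,TMA2,1986,Tubular carcinoma,1,pos,pos,neg,NA,neg,neg,1.0,Unknown
4-20,TMA1,1985,IDC,1,pos,pos,neg,neg,neg,neg,1.0,Luminal A
4-20,TMA2,1985,IDC,1,pos,pos,pos,neg,neg,neg,0.5,Luminal A
5-21,TMA1,1999,IDC,3,pos,neg,neg,3+,neg,neg,12.7,HER2
5-21,TMA2,1999,IDC,3,pos,neg,neg,3+,neg,neg,13.3,HER2
5-22,TMA1,1994,Mixed IDC and mucinous carcinoma,3,pos,pos,pos,neg,neg,neg,9.3,Luminal A
5-22,TMA2,1994,Mixed IDC and mucinous carcinoma,3,pos,pos,pos,neg,neg,neg,11.0,Luminal A
5-23,TMA1,1996,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,neg,neg,neg,1.7,Luminal A
5-23,TMA2,1996,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,neg,neg,neg,3.5,Luminal A
5-24,TMA1,1995,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,neg,neg,neg,16.0,Luminal B
5-24,TMA2,1995,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,neg,neg,neg,8.0,Luminal A
5-25,TMA1,1998,Invasive carcinoma with ductal and lobular features,2,pos,pos,neg,neg,neg,neg,5.7,Luminal A
5-25,TMA2,1998,Invasive carcinoma with ductal and lobular features,2,pos,pos,neg,neg,neg,neg,7.7,Luminal A
6-26,TMA1,2006,IDC,3,pos,pos,pos,3+,neg,neg,17.7,Luminal B
6-26,TMA2,2006,IDC,3,pos,pos,pos,3+,neg,neg,12.0,Luminal B
6-27,TMA1,2002,IDC,3,pos,neg,neg,3+,neg,neg,13.3,HER2
6-27,TMA2,2002,IDC,3,pos,neg,neg,3+,neg,neg,14.0,HER2
6-28,TMA1,2000,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,neg,neg,neg,5.7,Luminal A
6-28,TMA2,2000,Invasive carcinoma with ductal and lobular features,2,pos,pos,pos,NA,neg,neg,8.3,Luminal A or Luminal B
6-29,TMA1,2002,IDC with medullary features,3,pos,neg,neg,2+,pos,pos,6.3,Basal-like
6-29,TMA2,2002,IDC with medullary features,3,pos,neg,neg,neg,pos,pos,7.7,Basal-like
6-30,TMA1,2000,IDC,3,pos,pos,pos,neg,neg,neg,6.3,Luminal A
6-30,TMA2,2000,IDC,3,pos,pos,pos,neg,neg,neg,6.7,Luminal A
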