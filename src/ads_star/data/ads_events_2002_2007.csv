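year,intervals
2002,"2/11-2/12, 3/6-3/9, 3/23-3/24, 3/31-4/1, 4/8-4/15, 4/17-4/19"
2003,"2/18-2/19, 2/23-2/25, 3/6-3/9, 3/25-3/30, 4/25-4/28"
2004,"1/1-1/4, 1/13-1/14, 1/21-1/22, 1/24-1/25, 2/6-2/12, 2/14-2/16, 2/26-2/27, 3/3-3/7, 4/2-4/4"
2005,"3/18-3/19, 11/29-11/30, 12/21-12/22"
2006,"3/19-3/20, 3/29-3/30, 4/20-4/21"
2007,"1/28-1/29, 4/2-4/3, 4/17-4/18, 12/30-12/31"
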